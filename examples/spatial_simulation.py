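"""Run the spatial replicator simulation on a small field.

Molecules diffuse on a toroidal grid, bind via complementary dangling
ends, and complexes with a catalytic 5'-presenting strand replicate the
template into adjacent empty space with mutation.  Here a designed unit
of replication (seeded together with its complementary strand) grows a
mutant cloud at mu = 0.02.
"""

from rnaqs.grid import AbundanceObserver, SimParams, World
from rnaqs.folding import NussinovFoldEngine
from rnaqs.phenotype import reverse_complement

UNIT = "CCCCCUUUUUUUAACCCCUUAACCAAUUCCCCAAUUCCAAAAACCCCCCC"

params = SimParams(width=48, height=48, mu=0.02)
world = World(params, NussinovFoldEngine(), seed=7)
world.populate([UNIT, reverse_complement(UNIT)], density=0.2)

obs = AbundanceObserver()
world.add_observer(obs, interval=10)
world.run(50)

frame = obs.frame()
print(frame.to_string(index=False))
print()
print("columns: per-class molecule counts every 10 Monte Carlo steps on a")
print("48x48 field; 'complexed' molecules are currently bound in a pair.")
print("Units replicate, mutants fan out into the nonviable classes, and")
print("decay (d=0.03) balances growth.")
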