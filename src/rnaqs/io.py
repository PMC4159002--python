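"""FASTA and table I/O, run configuration, fixture generation.

Config files are INI-style with sections [sim], [energy], [fold], [ode],
[optimizer].  All tabular outputs are TSV with a provenance header
(comment lines recording the config hash, seed and fold-engine identity)
so any result file can be traced to the run that produced it.
"""

from __future__ import annotations

import configparser
import hashlib
import io as _io
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energy import EnergyParams
from .folding import get_engine
from .grid import SimParams
from .optimize import OptimizerParams
from .seq import RNA_ALPHABET


def read_fasta(path) -> list:
    """Read (id, sequence) pairs; DNA T is mapped to U with a warning."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "T" in seq:
            warnings.warn(f"record {rec.id}: DNA alphabet detected, mapping T->U")
            seq = seq.replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"record {rec.id}: invalid symbols {sorted(bad)}")
        records.append((rec.id, seq))
    return records


def write_fasta(records, path):
    """Write (id, sequence) pairs to FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class RunConfig:
    """Bundle of all configurable parameters plus run-level settings."""

    sim: SimParams = field(default_factory=SimParams)
    energy: EnergyParams = field(default_factory=EnergyParams)
    fold_engine: str = "mfe"          # [fold].engine: mfe | fallback
    optimizer: OptimizerParams = field(default_factory=OptimizerParams)
    seed: int = 0
    outdir: str = "."

    def engine(self):
        return get_engine(self.fold_engine)

    def config_hash(self) -> str:
        text = repr((asdict(self.sim), asdict(self.energy), self.fold_engine,
                     asdict(self.optimizer), self.seed))
        return hashlib.sha1(text.encode()).hexdigest()[:12]

    def provenance(self, engine=None) -> list:
        eng = engine.name if engine is not None else self.fold_engine
        return [f"# config: {self.config_hash()}",
                f"# seed: {self.seed}",
                f"# engine: {eng}"]


def _coerce(dc_type, section):
    kwargs = {}
    for f in fields(dc_type):
        if f.name not in section:
            continue
        raw = section[f.name]
        if f.type in ("int", int):
            kwargs[f.name] = int(raw)
        elif f.type in ("float", float):
            kwargs[f.name] = float(raw)
        elif f.type in ("bool", bool):
            kwargs[f.name] = raw.strip().lower() in ("1", "true", "yes")
        else:
            kwargs[f.name] = raw
    return dc_type(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig from an INI file; missing keys keep defaults."""
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    cfg = RunConfig()
    if cp.has_section("sim"):
        cfg.sim = _coerce(SimParams, cp["sim"])
    if cp.has_section("energy"):
        cfg.energy = _coerce(EnergyParams, cp["energy"])
    if cp.has_section("optimizer"):
        cfg.optimizer = _coerce(OptimizerParams, cp["optimizer"])
    if cp.has_section("fold"):
        cfg.fold_engine = cp["fold"].get("engine", cfg.fold_engine)
    if cp.has_section("run"):
        cfg.seed = cp["run"].getint("seed", cfg.seed)
        cfg.outdir = cp["run"].get("outdir", cfg.outdir)
    return cfg


def save_config(cfg: RunConfig, path):
    cp = configparser.ConfigParser()
    cp["sim"] = {k: str(v) for k, v in asdict(cfg.sim).items()}
    cp["energy"] = {k: str(v) for k, v in asdict(cfg.energy).items()}
    cp["fold"] = {"engine": cfg.fold_engine}
    cp["optimizer"] = {k: str(v) for k, v in asdict(cfg.optimizer).items()}
    cp["run"] = {"seed": str(cfg.seed), "outdir": str(cfg.outdir)}
    with open(path, "w") as fh:
        cp.write(fh)


def write_table(df, path, header_lines=()):
    """Write a DataFrame as TSV with provenance comment lines on top."""
    buf = _io.StringIO()
    for line in header_lines:
        buf.write(line.rstrip("\n") + "\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")


def generate_fixtures(kind: str, n: int, seed: int, engine, outdir,
                      length: int = 50, energy: EnergyParams = None):
    """Reproducible fixture files for tests and examples.

    * random_sequences: n uniform random RNA sequences (FASTA);
    * random_units: units of replication screened from random sequences
      (FASTA; screening continues until n units are found or 500*n draws);
    * toy_world: a small populated world snapshot (text grid + TSV of
      per-cell sequences).
    """
    import numpy as np

    from .energy import DEFAULT_ENERGY
    from .phenotype import FuncClass, genotype_of
    from .seq import random_sequence

    energy = energy or DEFAULT_ENERGY
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if kind == "random_sequences":
        recs = [(f"rand{i}", random_sequence(length, rng)) for i in range(n)]
        out = outdir / "random_sequences.fasta"
        write_fasta(recs, out)
        return [out]
    if kind == "random_units":
        units, tries = [], 0
        while len(units) < n and tries < 500 * n:
            seq = random_sequence(length, rng)
            tries += 1
            if genotype_of(seq, engine, energy).func_class is FuncClass.UNIT_OF_REPLICATION:
                units.append((f"unit{len(units)}", seq))
        out = outdir / "random_units.fasta"
        write_fasta(units, out)
        return [out]
    if kind == "toy_world":
        from .grid import SimParams, World

        params = SimParams(width=16, height=16, seq_length=length)
        world = World(params, engine, energy, seed=seed)
        seqs = []
        while len(seqs) < 3:
            seq = random_sequence(length, rng)
            seqs.append(seq)
        world.populate(seqs, density=float(min(1.0, n / 256)))
        import pandas as pd

        grid_path = outdir / "toy_world_grid.txt"
        grid_path.write_text("\n".join(world.snapshot()) + "\n")
        rows = [{"x": m.pos[0], "y": m.pos[1], "sequence": m.sequence}
                for m in sorted(world.molecules(), key=lambda m: (m.pos[1], m.pos[0]))]
        seq_path = outdir / "toy_world_cells.tsv"
        write_table(pd.DataFrame(rows), seq_path)
        return [grid_path, seq_path]
    raise ValueError(f"unknown fixture kind {kind!r}")
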