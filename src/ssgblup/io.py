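"""File formats: pedigree/phenotype CSV, dosage TSV, PLINK .raw/.map, YAML config.

All readers validate their input and report the 1-based line number of the
first malformed entry. Writers round-trip exactly with the readers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .grm import HInverseParams
from .mme import ModelSpec, TraitDataset, VarianceComponents
from .pedigree import Pedigree
from .qc import GenotypeMatrix, MarkerMap, QCReport, QCThresholds
from .simulate import SimulatedPopulation


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- pedigree

def read_pedigree_csv(path) -> Pedigree:
    """id,sire,dam records; 0/empty = unknown parent; header required."""
    path = Path(path)
    records = []
    with open(path) as fh:
        header = fh.readline()
        cols = [c.strip().lower() for c in header.strip().split(",")]
        if cols[:3] != ["id", "sire", "dam"]:
            raise FormatError(f"{path.name} line 1: expected header 'id,sire,dam', got {header.strip()!r}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.rstrip("\n").split(",")]
            if len(parts) < 3:
                raise FormatError(f"{path.name} line {ln}: expected 3 comma-separated fields")
            records.append((parts[0], parts[1], parts[2]))
    try:
        return Pedigree.from_records(records)
    except ValueError as e:
        raise FormatError(f"{path.name}: {e}") from e


def write_pedigree_csv(pedigree: Pedigree, path):
    with open(path, "w") as fh:
        fh.write("id,sire,dam\n")
        for a, s, d in pedigree.to_records():
            fh.write(f"{a},{s},{d}\n")


# -------------------------------------------------------------- phenotypes

PHENO_COLUMNS = ["id", "cg", "sex", "weight", "trait"]


def read_phenotypes_csv(path, trait_col: str = "trait") -> TraitDataset:
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str, "cg": str, "sex": str})
    missing = [c for c in ("id", trait_col) if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name} line 1: missing column(s) {missing}")
    bad = df[trait_col].isna() | ~df[trait_col].map(np.isreal)
    if bad.any():
        ln = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 1-based
        raise FormatError(f"{path.name} line {ln}: non-numeric trait value")
    return TraitDataset(df)


def write_phenotypes_csv(data: TraitDataset, path):
    data.data.to_csv(path, index=False, float_format="%.6g")


# --------------------------------------------------------------- genotypes

def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Plain dosage TSV: header 'animal_id<TAB>snp...', entries 0/1/2/NA."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "animal_id":
        raise FormatError(f"{path.name} line 1: first column must be 'animal_id'")
    snp_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy()
    dos = np.full(raw.shape, np.nan)
    valid = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan, "": np.nan}
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            v = raw[i, j]
            v = "NA" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
            if v not in valid:
                raise FormatError(
                    f"{path.name} line {i + 2}: invalid dosage {v!r} for SNP {snp_ids[j]!r}")
            dos[i, j] = valid[v]
    return GenotypeMatrix(dos, [str(a) for a in df["animal_id"]], snp_ids)


def write_genotypes_tsv(gm: GenotypeMatrix, path):
    with open(path, "w") as fh:
        fh.write("animal_id\t" + "\t".join(gm.snp_ids) + "\n")
        for i, a in enumerate(gm.animal_ids):
            row = ["NA" if np.isnan(v) else str(int(v)) if v == int(v) else f"{v:.4f}"
                   for v in gm.dosages[i]]
            fh.write(a + "\t" + "\t".join(row) + "\n")


def read_plink_raw(path) -> GenotypeMatrix:
    """PLINK .raw additive coding: FID IID PAT MAT SEX PHENOTYPE snp_A ..."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise FormatError(f"{path.name} line 1: not a PLINK .raw header")
        snp_ids = [c.rsplit("_", 1)[0] for c in header[6:]]
        animals, rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + len(snp_ids):
                raise FormatError(f"{path.name} line {ln}: expected {6 + len(snp_ids)} fields")
            animals.append(parts[1])
            row = []
            for j, v in enumerate(parts[6:]):
                if v in ("NA", "-9"):
                    row.append(np.nan)
                elif v in ("0", "1", "2"):
                    row.append(float(v))
                else:
                    raise FormatError(
                        f"{path.name} line {ln}: invalid dosage {v!r} for SNP {snp_ids[j]!r}")
            rows.append(row)
    return GenotypeMatrix(np.array(rows, float), animals, snp_ids)


def write_plink_raw(gm: GenotypeMatrix, path, counted_allele: str = "A"):
    with open(path, "w") as fh:
        fh.write("FID IID PAT MAT SEX PHENOTYPE "
                 + " ".join(f"{s}_{counted_allele}" for s in gm.snp_ids) + "\n")
        for i, a in enumerate(gm.animal_ids):
            row = ["NA" if np.isnan(v) else str(int(v)) for v in gm.dosages[i]]
            fh.write(f"{a} {a} 0 0 0 -9 " + " ".join(row) + "\n")


def read_plink_map(path) -> MarkerMap:
    """PLINK .map: chrom, snp id, cM, bp position (whitespace separated)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{path.name} line {ln}: expected 4 fields (chrom id cM bp)")
            try:
                rows.append((int(parts[0]), parts[1], float(parts[2]), int(parts[3])))
            except ValueError:
                raise FormatError(f"{path.name} line {ln}: malformed map entry {line.strip()!r}")
    return MarkerMap(pd.DataFrame(rows, columns=["chrom", "snp_id", "cm", "pos"]))


def write_plink_map(marker_map: MarkerMap, path):
    marker_map.frame.to_csv(path, sep="\t", header=False, index=False,
                            columns=["chrom", "snp_id", "cm", "pos"])


# ------------------------------------------------------------ matrices etc.

def write_matrix_tsv(values: np.ndarray, ids, path):
    pd.DataFrame(np.asarray(values), index=list(ids), columns=list(ids)) \
        .to_csv(path, sep="\t", float_format="%.10g")


def write_solutions_tsv(result, path):
    df = pd.DataFrame({"id": result.u_hat.index, "ebv": result.u_hat.to_numpy()})
    if result.pev is not None:
        df["pev"] = result.pev.to_numpy()
        df["reliability"] = result.reliability.to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_qc_report(report: QCReport, path):
    with open(path, "w") as fh:
        fh.write(report.to_frame().to_csv(sep="\t", index=False))
        fh.write(f"final_animals\t{report.final_animals}\n")
        fh.write(f"final_snps\t{report.final_snps}\n")
        for note in report.notes:
            fh.write(f"# {note}\n")


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """One YAML drives a whole evaluation; scenarios are named blocks."""

    pedigree: str
    phenotypes: str
    genotypes: Optional[str] = None
    marker_map: Optional[str] = None
    trait: str = "trait"
    factors: tuple[str, ...] = ("cg", "sex")
    covariates: tuple[str, ...] = ()
    sigma2_a: Optional[float] = None  # None => estimate by REML
    sigma2_e: Optional[float] = None
    h_params: HInverseParams = field(default_factory=HInverseParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    n_iterations: int = 3
    validated_ids: Optional[str] = None  # path to an id list, one per line
    seed: int = 0
    out_dir: str = "results"

    def model(self) -> ModelSpec:
        return ModelSpec(self.trait, self.factors, self.covariates)

    def variance_components(self) -> Optional[VarianceComponents]:
        if self.sigma2_a is None or self.sigma2_e is None:
            return None
        return VarianceComponents(self.sigma2_a, self.sigma2_e)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("pedigree", "phenotypes"):
            if key not in raw:
                raise FormatError(f"run config {path}: missing required key {key!r}")
        if "h_params" in raw:
            raw["h_params"] = HInverseParams(**raw["h_params"])
        if "qc" in raw:
            raw["qc"] = QCThresholds(**raw["qc"])
        if "factors" in raw:
            raw["factors"] = tuple(raw["factors"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        known = set(cls.__dataclass_fields__)
        extra = set(raw) - known
        if extra:
            raise FormatError(f"run config {path}: unknown keys {sorted(extra)}")
        return cls(**raw)


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, timings, checksums."""

    config: dict
    seed: int
    version: str = "0.1.0"
    stages: list = field(default_factory=list)  # (stage, seconds, counts)
    checksums: dict = field(default_factory=dict)

    def add_stage(self, name: str, seconds: float, **counts):
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **counts})

    def add_checksum(self, path):
        p = Path(path)
        h = hashlib.sha256(p.read_bytes()).hexdigest()
        self.checksums[p.name] = h

    def write(self, path):
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed,
                       "version": self.version, "stages": self.stages,
                       "checksums": self.checksums}, fh, indent=2, default=str)


def write_population(pop: SimulatedPopulation, out_dir, include_raw: bool = True) -> dict:
    """Write a simulated population: pedigree, phenotypes, genotypes, map, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.csv",
        "phenotypes": out / "phenotypes.csv",
        "genotypes": out / "genotypes.tsv",
        "marker_map": out / "markers.map",
        "tbv": out / "true_breeding_values.tsv",
        "qtl": out / "qtl.tsv",
    }
    write_pedigree_csv(pop.pedigree, paths["pedigree"])
    write_phenotypes_csv(pop.phenotypes, paths["phenotypes"])
    gm = pop.genotyped_matrix()
    write_genotypes_tsv(gm, paths["genotypes"])
    write_plink_map(pop.marker_map, paths["marker_map"])
    pop.true_breeding_values.rename("tbv").to_csv(paths["tbv"], sep="\t",
                                                  index_label="id", float_format="%.8g")
    pd.DataFrame({
        "snp_id": [pop.genotypes.snp_ids[j] for j in pop.qtl_indices],
        "effect": pop.qtl_effects,
    }).to_csv(paths["qtl"], sep="\t", index=False, float_format="%.8g")
    if include_raw:
        paths["raw"] = out / "genotypes.raw"
        write_plink_raw(gm, paths["raw"])
    return {k: str(v) for k, v in paths.items()}
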