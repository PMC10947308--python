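"""Domain types, file readers/writers, configuration and provenance.

Shared contracts for the cross-simulation, haplotype-calling, linkage-map,
QTL-scan and morphology modules.  Coordinates are 0-based half-open
internally; 1-based only at the VCF boundary.  Missing genotypes are an
explicit value (-1 internally, "-" in tabular files), never an absence.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("snapmap")

# genotype codes for biallelic SNPs
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1
SNP_CODE_TO_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "-"}
SNP_STR_TO_CODE = {v: k for k, v in SNP_CODE_TO_STR.items()}

# species-origin codes (b = lowland parent, r = alpine parent)
BB, BR, RR = 0, 1, 2
SPECIES_CODE_TO_STR = {0: "bb", 1: "br", 2: "rr", -1: "-"}
SPECIES_STR_TO_CODE = {v: k for k, v in SPECIES_CODE_TO_STR.items()}

ROLES = ("parentB", "parentR", "F1a", "F1b", "F2")


@dataclass
class SnpCall:
    """One biallelic SNP with genotypes for every individual in the dataset."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotypes: np.ndarray  # int8, aligned with SnpMatrix.samples

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.ref == self.alt:
            raise ValueError("REF and ALT alleles must differ")


@dataclass
class SnpMatrix:
    """SNP-by-sample genotype matrix with sample roles attached.

    ``geno`` is int8 with values {0: hom-ref, 1: het, 2: hom-alt, -1: missing};
    rows are SNPs sorted by (chrom, pos), columns follow ``samples``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray
    samples: list[str]
    roles: dict[str, str]
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.pos)

    def __iter__(self):
        for i in range(len(self)):
            yield SnpCall(self.chrom[i], int(self.pos[i]), str(self.ref[i]),
                          str(self.alt[i]), self.geno[i])

    def columns_for_role(self, role: str) -> list[int]:
        return [j for j, s in enumerate(self.samples) if self.roles[s] == role]

    @property
    def f2_columns(self) -> list[int]:
        return self.columns_for_role("F2")


@dataclass
class RadLocusGenotypes:
    """One binned RAD locus: haplotype alleles, origins and F2 calls.

    ``haplotypes`` are tuples of 0/1 SNP alleles over ``snp_pos``;
    ``diplotypes`` is (n_individuals, 2) of haplotype indices (-1 missing);
    ``species_code`` is int8 {0: bb, 1: br, 2: rr, -1: missing}.
    """

    chrom: str
    start: int
    end: int  # half-open
    snp_pos: np.ndarray
    haplotypes: list[tuple[int, ...]]
    origins: list[str | None] = field(default_factory=list)  # 'b'/'r'/None
    diplotypes: np.ndarray | None = None
    species_code: np.ndarray | None = None
    flag: str | None = None  # None | 'ambiguous' | 'inconsistent'

    @property
    def marker_id(self) -> str:
        return f"{self.chrom}:{self.start}"

    @property
    def origin_informative(self) -> bool:
        """All haplotypes segregating in the F2 resolve to a parental origin."""
        if self.diplotypes is None or not self.origins:
            return False
        seg = {h for pair in self.diplotypes for h in pair if h >= 0}
        return bool(seg) and all(self.origins[h] in ("b", "r") for h in seg)


@dataclass
class GeneticMap:
    """Ordered linkage groups with Kosambi cM positions.

    ``table`` columns: marker, group, cm, chrom, bp.  Positions are
    non-decreasing within a group.
    """

    table: pd.DataFrame
    lod_group: float
    lod_order: float

    def __post_init__(self) -> None:
        for g, sub in self.table.groupby("group"):
            if not np.all(np.diff(sub["cm"].to_numpy()) >= -1e-9):
                raise ValueError(f"cM positions decrease within group {g}")

    @property
    def groups(self) -> list[int]:
        return sorted(self.table["group"].unique())

    def group_table(self, g: int) -> pd.DataFrame:
        return self.table[self.table["group"] == g]

    @property
    def total_length_cm(self) -> float:
        return float(sum(self.group_table(g)["cm"].max() - self.group_table(g)["cm"].min()
                         for g in self.groups))


@dataclass
class TrdResult:
    """Per-locus transmission-ratio-distortion tests and flagged intervals."""

    table: pd.DataFrame  # marker, b_count, n_alleles, chi2_allele, p_allele,
    #                       n_bb, n_br, n_rr, chi2_phase, p_phase, flagged
    alpha: float
    bonferroni_alpha: float
    flagged_markers: list[str]
    map_fraction_cm: float | None  # fraction of map length inside flagged intervals


@dataclass
class Qtl:
    trait: str
    group: int
    pos_cm: float
    additive: float
    dominance: float
    pve: float
    lod: float
    interval_1lod: tuple[float, float]
    interval_2lod: tuple[float, float]


@dataclass
class QtlScanResult:
    trait: str
    positions: pd.DataFrame  # group, cm
    lod: np.ndarray
    threshold: float
    alpha: float
    n_perm: int
    qtl: list[Qtl] = field(default_factory=list)
    pve_total: float = 0.0


@dataclass
class IndexWeights:
    """Discriminant morphology-index weights with the training normalization."""

    characters: list[str]
    mean: np.ndarray  # training means (after log transform where flagged)
    sd: np.ndarray
    weights: np.ndarray
    log_chars: tuple[str, ...]
    positive_class: str  # class whose training mean index is positive


@dataclass
class AnalysisConfig:
    """Thresholds governing the pipeline; the single source of defaults."""

    bin_window: int = 1500
    max_missing: float = 0.25
    lod_group: float = 6.0
    lod_order: float = 10.0
    grid_step: float = 1.0
    genotype_error: float = 0.001
    alpha: float = 0.05
    n_perm: int = 1000
    singleton_threshold: int = 5
    seed: int = 1

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a sectioned TOML config; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    flat: dict = {}
    for key, value in raw.items():
        if isinstance(value, dict):
            flat.update(value)
        else:
            flat[key] = value
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(flat) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**flat)


# ---------------------------------------------------------------------------
# readers


def read_sample_roles(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "role"} <= set(df.columns):
        raise ValueError("sample-role table needs columns 'sample' and 'role'")
    roles = dict(zip(df["sample"], df["role"]))
    bad = {r for r in roles.values() if r not in ROLES}
    if bad:
        raise ValueError(f"unknown roles: {sorted(bad)}; expected one of {ROLES}")
    return roles


def _attach_roles(samples: Sequence[str], roles: dict[str, str]) -> dict[str, str]:
    missing = [s for s in samples if s not in roles]
    if missing:
        raise ValueError(f"samples without a role: {missing[:5]}")
    extra = [s for s in roles if s not in samples]
    if extra:
        raise ValueError(f"unknown sample ids in role table: {extra[:5]}")
    return {s: roles[s] for s in samples}


def read_snp_matrix(path: str | Path, roles_path: str | Path,
                    format: str | None = None) -> SnpMatrix:
    """Read SNP genotypes from VCF or genotype TSV, with a sample-role sidecar.

    Non-biallelic records are rejected (counted in ``n_rejected`` and logged).
    Coordinates are normalized to 0-based.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" or path.name.endswith(".vcf.gz") else "tsv"
    roles = read_sample_roles(roles_path)
    if format == "vcf":
        mat = _read_vcf(path)
    elif format == "tsv":
        mat = _read_genotype_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    mat.roles = _attach_roles(mat.samples, roles)
    return mat


def _read_vcf(path: Path) -> SnpMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, geno = [], [], [], [], []
    n_rejected = 0
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0, 1, -1, 2], dtype=np.int8)
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_rejected += 1
            continue
        chrom.append(rec.CHROM)
        pos.append(rec.POS - 1)  # to 0-based
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        geno.append(remap[rec.gt_types])
    if n_rejected:
        logger.warning("rejected %d non-biallelic VCF records", n_rejected)
    mat = SnpMatrix(np.array(chrom), np.array(pos, dtype=np.int64),
                    np.array(ref), np.array(alt),
                    np.array(geno, dtype=np.int8), samples, {}, n_rejected)
    return _sort_snps(mat)


def _read_genotype_tsv(path: Path) -> SnpMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["chrom", "pos", "ref", "alt"]
    samples = [c for c in df.columns if c not in fixed]
    geno = np.empty((len(df), len(samples)), dtype=np.int8)
    for j, s in enumerate(samples):
        try:
            geno[:, j] = [SNP_STR_TO_CODE[v] for v in df[s]]
        except KeyError as e:
            raise ValueError(f"bad genotype code {e} in column {s}") from e
    mat = SnpMatrix(df["chrom"].to_numpy(), df["pos"].to_numpy(np.int64),
                    df["ref"].to_numpy(), df["alt"].to_numpy(), geno,
                    samples, {})
    return _sort_snps(mat)


def _sort_snps(mat: SnpMatrix) -> SnpMatrix:
    order = np.lexsort((mat.pos, mat.chrom))
    mat.chrom = mat.chrom[order]
    mat.pos = mat.pos[order]
    mat.ref = mat.ref[order]
    mat.alt = mat.alt[order]
    mat.geno = mat.geno[order]
    return mat


def write_genotype_tsv(mat: SnpMatrix, path: str | Path) -> None:
    cols = {"chrom": mat.chrom, "pos": mat.pos, "ref": mat.ref, "alt": mat.alt}
    for j, s in enumerate(mat.samples):
        cols[s] = [SNP_CODE_TO_STR[int(g)] for g in mat.geno[:, j]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_vcf(mat: SnpMatrix, path: str | Path) -> None:
    """Write a minimal uncompressed VCF (diploid unphased GT only)."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(mat.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(mat.samples) + "\n")
        for i in range(len(mat)):
            row = [str(mat.chrom[i]), str(int(mat.pos[i]) + 1), ".",
                   str(mat.ref[i]), str(mat.alt[i]), ".", ".", ".", "GT"]
            row += [gt[int(g)] for g in mat.geno[i]]
            fh.write("\t".join(row) + "\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "individual" in df.columns:
        df = df.set_index("individual")
    return df


def read_species_coded_tsv(path: str | Path) -> pd.DataFrame:
    """Species-origin genotype table: marker, group?, chrom, bp, then F2 codes."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_species_coded_tsv(loci: Iterable[RadLocusGenotypes], f2_ids: Sequence[str],
                            path: str | Path) -> None:
    rows = []
    for loc in loci:
        row = {"marker": loc.marker_id, "chrom": loc.chrom, "bp": loc.start}
        codes = loc.species_code
        for s, c in zip(f2_ids, codes):
            row[s] = SPECIES_CODE_TO_STR[int(c)]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# writers


def write_map_tsv(gmap: GeneticMap, path: str | Path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False,
                      columns=["marker", "group", "cm", "chrom", "bp"],
                      float_format="%.6f")


def read_map_tsv(path: str | Path, lod_group: float = 6.0,
                 lod_order: float = 10.0) -> GeneticMap:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneticMap(table, lod_group, lod_order)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(obj, path: str | Path, config: AnalysisConfig | None = None,
                  seed: int | None = None) -> None:
    """Serialize a result object with a provenance block (config hash, seed)."""
    path = Path(path)
    if isinstance(obj, GeneticMap):
        write_map_tsv(obj, path)
        return
    payload = {"provenance": {"config_hash": config.hash() if config else None,
                              "seed": seed},
               "result": _jsonable(obj)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
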