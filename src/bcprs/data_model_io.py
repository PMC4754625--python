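"""Domain types and file I/O.

Container types for SNP weight panels, genotype dosage matrices, cohort
phenotype tables, and age-indexed rate tables, plus readers/writers for the
tab-separated / CSV / VCF formats every other module consumes.

Conventions
-----------
* Dosages count copies of the *effect allele* and live in {0, 1, 2} with
  ``NaN`` as the missing sentinel — missing is never conflated with 0.
* VCF positions are 1-based per the standard and stored untouched.
* Alleles are matched literally (no strand inference); for ambiguous A/T and
  C/G variants the panel file is the source of truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("bcprs")

#: Missing-dosage sentinel (kept distinct from 0).
MISSING = np.nan

VALID_ALLELES = frozenset("ACGT")

PANEL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele", "eaf",
    "beta_overall", "beta_erpos", "beta_erneg", "region_id",
]

ENDPOINTS = ("overall", "erpos", "erneg")

COHORT_COLUMNS = [
    "individual_id", "status", "age", "er_status", "family_history", "study_id",
    "pc1", "pc2", "pc3", "pc4", "pc5", "pc6", "pc7",
]
PC_COLUMNS = ["pc1", "pc2", "pc3", "pc4", "pc5", "pc6", "pc7"]

RATE_COLUMNS = ["age", "incidence", "mortality", "er_pos_prop"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SNPPanel:
    """Per-SNP effect alleles, frequencies and per-allele log odds ratios.

    One row per susceptibility variant: effect/other allele, effect-allele
    frequency ``eaf``, per-allele log ORs for the three disease endpoints
    (overall, ER-positive, ER-negative), and a ``region_id`` grouping linked
    variants from the same susceptibility region.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        ids = self.df["snp_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate snp_id: {dup.iloc[0]!r}")
        eaf = self.df["eaf"].to_numpy(float)
        bad = np.flatnonzero(~((eaf > 0.0) & (eaf < 1.0)))
        if len(bad):
            raise ValueError(
                f"eaf outside (0,1) at row {bad[0] + 1} "
                f"(snp_id={ids.iloc[bad[0]]!r}, eaf={eaf[bad[0]]})"
            )
        for col in ("beta_overall", "beta_erpos", "beta_erneg"):
            vals = self.df[col].to_numpy(float)
            if not np.all(np.isfinite(vals)):
                row = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise ValueError(f"non-finite {col} at row {row + 1}")
        for _, rec in self.df.iterrows():
            ea, oa = rec["effect_allele"], rec["other_allele"]
            if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
                raise ValueError(f"invalid alleles for {rec['snp_id']}: {ea}/{oa}")
            if ea == oa:
                raise ValueError(f"effect_allele == other_allele for {rec['snp_id']}")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def eaf(self) -> np.ndarray:
        return self.df["eaf"].to_numpy(float)

    def betas(self, endpoint: str = "overall") -> np.ndarray:
        """Per-allele log OR column for one endpoint."""
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
        return self.df[f"beta_{endpoint}"].to_numpy(float)


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs effect-allele dosages in {0, 1, 2, NaN}."""

    individual_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float, shape (n_individuals, n_snps)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    def validate(self) -> None:
        n, k = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValueError(
                f"{len(self.individual_ids)} individual ids but {n} dosage rows"
            )
        if k != len(self.snp_ids):
            raise ValueError(f"{len(self.snp_ids)} snp ids but {k} dosage columns")
        vals = self.dosages[~np.isnan(self.dosages)]
        if len(vals) and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage value {bad} outside {{0,1,2,missing}}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class CohortTable:
    """Case-control phenotypes: status, age, ER subtype, family history,
    study membership and seven principal components.

    ``liability`` optionally carries the latent total polygenic liability
    retained by the synthetic generator (needed to simulate family history);
    it is never read from disk.
    """

    df: pd.DataFrame
    liability: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table is missing columns: {missing}")
        status = self.df["status"].to_numpy()
        if not np.all(np.isin(status, (0, 1))):
            raise ValueError("status must be 0 (control) or 1 (case)")
        age = self.df["age"].to_numpy(float)
        if np.any((age < 18) | (age > 100)):
            raise ValueError("age outside [18, 100]")
        er = self.df["er_status"].to_numpy()
        ok_er = np.isin(er, ("pos", "neg", "unknown"))
        if not np.all(ok_er):
            raise ValueError(f"invalid er_status value {er[~ok_er][0]!r}")
        if np.any((status == 0) & (er != "unknown")):
            raise ValueError("controls must have er_status == 'unknown'")
        fh = self.df["family_history"].to_numpy(float)
        fh_obs = fh[~np.isnan(fh)]
        if len(fh_obs) and not np.all(np.isin(fh_obs, (0.0, 1.0))):
            raise ValueError("family_history must be 0, 1 or missing")
        if self.liability is not None and len(self.liability) != len(self.df):
            raise ValueError("liability length does not match cohort rows")

    @property
    def status(self) -> np.ndarray:
        return self.df["status"].to_numpy(int)

    @property
    def n(self) -> int:
        return len(self.df)

    def covariate_frame(self) -> pd.DataFrame:
        """Study + 7 PCs, the standard adjustment set for every fit."""
        return self.df[["study_id"] + PC_COLUMNS]


@dataclass
class RateTable:
    """Age-indexed population rates: breast-cancer incidence λ(t), competing
    (other-cause) mortality μ(t), and the ER-positive proportion π+(t) of
    incident cases, per person-year, on a contiguous integer age grid."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in RATE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"rate table is missing columns: {missing}")
        ages = self.df["age"].to_numpy(int)
        gaps = np.flatnonzero(np.diff(ages) != 1)
        if len(gaps):
            raise ValueError(
                f"rate table ages are not contiguous: gap after age {ages[gaps[0]]} "
                f"(next age {ages[gaps[0] + 1]})"
            )
        if np.any(self.df["incidence"].to_numpy(float) < 0):
            raise ValueError("negative incidence rate")
        if np.any(self.df["mortality"].to_numpy(float) < 0):
            raise ValueError("negative mortality rate")
        pp = self.df["er_pos_prop"].to_numpy(float)
        if np.any((pp < 0) | (pp > 1)):
            raise ValueError("er_pos_prop outside [0, 1]")

    @property
    def ages(self) -> np.ndarray:
        return self.df["age"].to_numpy(int)

    def incidence_on(self, age_start: int, age_end: int) -> np.ndarray:
        return self._col_on("incidence", age_start, age_end)

    def mortality_on(self, age_start: int, age_end: int) -> np.ndarray:
        return self._col_on("mortality", age_start, age_end)

    def er_pos_prop_on(self, age_start: int, age_end: int) -> np.ndarray:
        return self._col_on("er_pos_prop", age_start, age_end)

    def _col_on(self, col: str, age_start: int, age_end: int) -> np.ndarray:
        ages = self.ages
        if age_start < ages[0] or age_end > ages[-1]:
            raise ValueError(
                f"requested ages [{age_start}, {age_end}] outside rate table "
                f"range [{ages[0]}, {ages[-1]}]"
            )
        lo = age_start - ages[0]
        hi = age_end - ages[0]
        return self.df[col].to_numpy(float)[lo:hi + 1]


#: Cumulative-fraction boundaries of the 11 percentile bins used throughout:
#: <1, 1–5, 5–10, 10–20, 20–40, 40–60 (reference), 60–80, 80–90, 90–95,
#: 95–99, >99.
DEFAULT_BIN_BOUNDARIES = (
    0.0, 0.01, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 0.90, 0.95, 0.99, 1.0,
)
DEFAULT_BIN_LABELS = (
    "<1", "1-5", "5-10", "10-20", "20-40", "40-60", "60-80", "80-90",
    "90-95", "95-99", ">99",
)


@dataclass
class PercentileScheme:
    """Ordered percentile bins as cumulative-fraction intervals (lower-open,
    upper-closed), with the middle quintile (40th–60th) as reference."""

    boundaries: tuple[float, ...] = DEFAULT_BIN_BOUNDARIES
    labels: tuple[str, ...] = DEFAULT_BIN_LABELS
    reference_label: str = "40-60"

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, float)
        if b[0] != 0.0 or b[-1] != 1.0 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must increase strictly from 0 to 1")
        if len(self.labels) != len(b) - 1:
            raise ValueError("need one label per bin")
        if self.reference_label not in self.labels:
            raise ValueError(f"reference bin {self.reference_label!r} not in labels")

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    @property
    def reference_index(self) -> int:
        return self.labels.index(self.reference_label)

    def intervals(self) -> list[tuple[float, float]]:
        b = self.boundaries
        return [(b[i], b[i + 1]) for i in range(len(b) - 1)]

    def bin_fractions(self) -> np.ndarray:
        return np.diff(np.asarray(self.boundaries, float))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> SNPPanel:
    """Read a SNP weight panel from a header-bearing TSV."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"snp_id": str, "chrom": str, "region_id": str})
    return SNPPanel(df[PANEL_COLUMNS] if set(PANEL_COLUMNS) <= set(df.columns) else df)


def write_panel(panel: SNPPanel, path: str | Path) -> None:
    """Write a panel as canonical TSV (column order fixed, full float repr)."""
    panel.df[PANEL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_genotypes(path: str | Path, panel: SNPPanel, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype dosage matrix, aligned to the panel's SNP order.

    TSV dialect: individuals as rows (first column ``individual_id``), SNPs as
    columns, cells in {0, 1, 2, NA}.  VCF dialect: per-sample DS field when
    present, otherwise the GT hard call converted to an effect-allele count.
    Variants whose REF/ALT orientation is flipped relative to the panel's
    (other, effect) alleles are recoded ``2 − dosage``; panel SNPs absent from
    the file become all-missing columns with a logged warning.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path, panel)
    if format == "vcf":
        return _read_genotypes_vcf(path, panel)
    raise ValueError(f"unknown genotype format {format!r} (expected 'tsv' or 'vcf')")


def _read_genotypes_tsv(path: str | Path, panel: SNPPanel) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str},
                     na_values=["NA"], float_precision="round_trip")
    if "individual_id" not in df.columns:
        raise ValueError("genotype TSV must have an 'individual_id' column")
    ids = list(df["individual_id"])
    n = len(ids)
    dos = np.full((n, panel.n_snps), np.nan)
    absent = []
    for j, sid in enumerate(panel.snp_ids):
        if sid in df.columns:
            dos[:, j] = df[sid].to_numpy(float)
        else:
            absent.append(sid)
    if absent:
        logger.warning("genotype TSV lacks %d panel SNP(s): %s — stored as missing",
                       len(absent), ", ".join(absent[:5]))
    return GenotypeMatrix(ids, panel.snp_ids, dos)


def _dosage_from_vcf_record(variant, n_samples: int) -> np.ndarray:
    """ALT-allele dosage per sample: DS field preferred, else GT hard call."""
    try:
        ds = variant.format("DS")
    except KeyError:
        ds = None
    if ds is not None:
        return np.asarray(ds, float).reshape(n_samples)
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt = np.asarray(variant.gt_types)
    dose = np.full(n_samples, np.nan)
    dose[gt == 0] = 0.0
    dose[gt == 1] = 1.0
    dose[gt == 3] = 2.0
    return dose


def _read_genotypes_vcf(path: str | Path, panel: SNPPanel) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    dos = np.full((n, panel.n_snps), np.nan)
    col_of = {sid: j for j, sid in enumerate(panel.snp_ids)}
    seen: set[str] = set()
    for variant in vcf:
        sid = variant.ID
        if sid not in col_of:
            continue
        j = col_of[sid]
        rec = panel.df.iloc[j]
        ref, alt = variant.REF, (variant.ALT[0] if variant.ALT else None)
        raw = _dosage_from_vcf_record(variant, n)
        if ref == rec["other_allele"] and alt == rec["effect_allele"]:
            dos[:, j] = raw
        elif ref == rec["effect_allele"] and alt == rec["other_allele"]:
            dos[:, j] = 2.0 - raw  # flipped orientation: ALT counts the other allele
        else:
            raise ValueError(
                f"VCF alleles {ref}/{alt} for {sid} incompatible with panel "
                f"{rec['other_allele']}/{rec['effect_allele']} in either orientation"
            )
        seen.add(sid)
    absent = [s for s in panel.snp_ids if s not in seen]
    if absent:
        logger.warning("VCF lacks %d panel SNP(s): %s — stored as missing",
                       len(absent), ", ".join(absent[:5]))
    vcf.close()
    return GenotypeMatrix(samples, panel.snp_ids, dos)


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.snp_ids)
    df.insert(0, "individual_id", genotypes.individual_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     float_precision="round_trip",
                     dtype={"individual_id": str, "study_id": str})
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_rates(path: str | Path) -> RateTable:
    """Read an age-indexed rate table from CSV (age, incidence, mortality,
    er_pos_prop); non-contiguous ages are a hard error naming the gap."""
    return RateTable(pd.read_csv(path, float_precision="round_trip"))


def write_rates(rates: RateTable, path: str | Path) -> None:
    rates.df.to_csv(path, index=False, float_format="%.17g")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for run provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(objects: dict, path: str | Path, seed: int | None = None,
                  config: dict | None = None) -> None:
    """Write analysis outputs plus a run-metadata block.

    ``objects`` maps names to DataFrames (written as sibling TSVs at full
    precision) or JSON-serialisable values (inlined).  The JSON file at
    ``path`` carries the metadata (seed, config hash) and inline results.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"seed": seed, "config_hash": config_hash(config) if config else None}
    inline: dict = {}
    for name, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            tsv = path.with_name(f"{path.stem}_{name}.tsv")
            obj.to_csv(tsv, sep="\t", index=False, na_rep="NA", float_format="%.17g")
            inline[name] = {"file": tsv.name}
        else:
            inline[name] = obj
    with open(path, "w") as fh:
        json.dump({"metadata": meta, "results": inline}, fh, indent=2, default=float)
        fh.write("\n")
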