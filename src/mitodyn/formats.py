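"""Call-table readers/writers (TSV and VCF) and run configuration.

All user-visible coordinates are 1-based inclusive. Call tables are TSV
with header ``sample_id position ref alt maf depth p_value filter``; the
VCF dialect is v4.2, single-sample, unphased, with the minor-allele
frequency carried as INFO/AF and depth as INFO/DP.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import pysam
import yaml

from mitodyn.calling import FILTER_PASS, HeteroplasmyCall

CALL_COLUMNS = ["sample_id", "position", "ref", "alt", "maf", "depth",
                "p_value", "filter"]


def calls_to_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    return pd.DataFrame(
        [{"sample_id": c.sample_id, "position": c.position, "ref": c.ref,
          "alt": c.alt, "maf": c.maf, "depth": c.depth,
          "p_value": c.p_value if c.p_value is not None else math.nan,
          "filter": c.filter} for c in calls],
        columns=CALL_COLUMNS,
    )


def frame_to_calls(df: pd.DataFrame) -> list[HeteroplasmyCall]:
    return [HeteroplasmyCall(
        position=int(r["position"]), ref=str(r["ref"]), alt=str(r["alt"]),
        maf=float(r["maf"]), depth=int(r["depth"]), sample_id=str(r["sample_id"]),
        p_value=None if pd.isna(r.get("p_value", math.nan)) else float(r["p_value"]),
        filter=str(r.get("filter", FILTER_PASS)))
        for _, r in df.iterrows()]


def _validate_call_frame(df: pd.DataFrame, path: str) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("position", "maf", "depth"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(values.isna() & df[col].notna()) if col != "maf" \
            else np.flatnonzero(values.isna())
        bad = np.flatnonzero(values.isna())
        if bad.size:
            raise ValueError(f"{path}: line {bad[0] + 2}: non-numeric {col!r}")
        df[col] = values
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if not 0.0 < row["maf"] <= 0.5:
            raise ValueError(
                f"{path}: line {line}: MAF {row['maf']} outside (0, 0.5] "
                "(minor-allele convention)")
        if row["depth"] <= 0:
            raise ValueError(f"{path}: line {line}: non-positive depth")
        if row["position"] < 1:
            raise ValueError(f"{path}: line {line}: position < 1")
    df["position"] = df["position"].astype(int)
    df["depth"] = df["depth"].astype(int)
    if "p_value" not in df.columns:
        df["p_value"] = math.nan
    if "filter" not in df.columns:
        df["filter"] = FILTER_PASS
    return df[CALL_COLUMNS]


def write_calls(calls, path: str, dialect: str = "tsv",
                contig: str = "mitogenome", contig_length: int | None = None) -> None:
    """Write a call table as TSV (default) or single-sample VCF v4.2."""
    df = calls_to_frame(calls)
    if dialect == "tsv":
        # %.17g guarantees float fields survive a write/read round trip
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif dialect == "vcf":
        _write_vcf(df, path, contig, contig_length)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_calls(path: str, dialect: str = "tsv") -> pd.DataFrame:
    """Read a call table; raises on malformed rows, naming the line."""
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if df.empty:
            return pd.DataFrame(columns=CALL_COLUMNS)
        return _validate_call_frame(df, path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_vcf(df: pd.DataFrame, path: str, contig: str,
               contig_length: int | None) -> None:
    samples = df["sample_id"].unique()
    if len(samples) > 1:
        raise ValueError("VCF output is single-sample; split the table first")
    sample = str(samples[0]) if len(samples) else "sample"
    header = pysam.VariantHeader()
    if contig_length is None:
        contig_length = int(df["position"].max()) if len(df) else 1
    header.contigs.add(contig, length=contig_length)
    header.add_meta("INFO", items=[("ID", "AF"), ("Number", "A"), ("Type", "Float"),
                                   ("Description", "Minor allele frequency")])
    header.add_meta("INFO", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                   ("Description", "Site depth")])
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for _, r in df.sort_values("position").iterrows():
            rec = vcf.new_record(contig=contig, start=int(r["position"]) - 1,
                                 alleles=(str(r["ref"]), str(r["alt"])))
            rec.info["AF"] = float(r["maf"])
            rec.info["DP"] = int(r["depth"])
            rec.samples[sample]["GT"] = (0, 1)
            rec.samples[sample].phased = False
            vcf.write(rec)


def _read_vcf(path: str) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(path) as vcf:
        sample = list(vcf.header.samples)[0] if vcf.header.samples else "sample"
        for rec in vcf:
            af = rec.info.get("AF")
            maf = float(af[0] if isinstance(af, tuple) else af)
            rows.append({"sample_id": sample, "position": rec.pos,
                         "ref": rec.ref, "alt": rec.alts[0], "maf": maf,
                         "depth": int(rec.info.get("DP", 0)),
                         "p_value": math.nan, "filter": FILTER_PASS})
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Effective pipeline settings.

    Every switch defaults to the decision the pipeline's documentation
    records for the matching ambiguity (strict thresholds, conditional
    accuracy, assayable-site FPR, linear-interpolation quartiles, no Yates
    correction, case-resampling bootstrap).
    """

    maf_min: float = 0.01
    cov_min: int = 1000
    alpha: float = 0.05
    pad: int = 500
    error_rate: float = 0.001
    genome_length: int = 16211
    coverage_grid: tuple = (50, 100, 250, 500, 1000, 2500, 5000, 10000, 25000)
    seed: int | None = None
    accuracy_denominator: str = "called"
    fpr_denominator: str = "assayable"
    quartile_method: str = "linear"
    iqr_multiplier: float = 2.0
    chi2_yates: bool = False
    bootstrap_parametric: bool = False
    bootstrap_replicates: int = 1000
    permutation_replicates: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError(f"maf_min {self.maf_min} outside [0, 0.5)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.cov_min < 0 or self.pad < 0:
            raise ValueError("cov_min and pad must be non-negative")
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError(f"error_rate {self.error_rate} outside [0, 0.25)")
        if self.accuracy_denominator not in ("called", "true"):
            raise ValueError("accuracy_denominator must be 'called' or 'true'")
        if self.fpr_denominator not in ("assayable", "calls"):
            raise ValueError("fpr_denominator must be 'assayable' or 'calls'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | None) -> RunConfig:
    """Load a YAML config; missing keys take defaults, unknown keys raise."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name: f for f in fields(RunConfig)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if key == "coverage_grid" and isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return RunConfig(**coerced)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from exc
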