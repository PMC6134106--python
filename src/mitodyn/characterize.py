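"""Heteroplasmy characterization: spectra, coding effects, enrichment.

Substitutions are binned into the four strand-symmetric classes -- one
transition class (G:C<->A:T) and three transversion classes (G:C<->T:A,
the signature of 8-oxo-guanine oxidative damage; A:T<->T:A; G:C<->C:G) --
which partition the 12 ordered single-base changes. Coding effects are
annotated under the vertebrate mitochondrial genetic code (translation
table 2), forced by the organism. Frequency spectra of call bins are
compared with two-sided Kolmogorov-Smirnov or Mann-Whitney U tests, and
per-partition site enrichment with Pearson's chi-square on a 2x2
heteroplasmic/homoplasmic x in-bin/out-of-bin table.

PROVEAN-style deleteriousness scoring is a web service and is replaced by
a pluggable scorer interface; the default BLOSUM62-based stand-in is *not*
equivalent to PROVEAN and its labels should not be compared with published
Deleterious/Neutral counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy import stats

from mitodyn.genome import Feature, Mitogenome

#: df=1 critical values commonly used for the enrichment flag
CHI2_CRIT_P05 = 3.841
CHI2_CRIT_P001 = 10.828

VERTEBRATE_MITO_TABLE = 2


class MutationClass(str, enum.Enum):
    GC_AT_TRANSITION = "GC_AT_transition"
    GC_TA_TRANSVERSION = "GC_TA_transversion"   # oxidative class
    AT_TA_TRANSVERSION = "AT_TA_transversion"
    GC_CG_TRANSVERSION = "GC_CG_transversion"


_CLASS_OF_PAIR = {
    ("G", "A"): MutationClass.GC_AT_TRANSITION,
    ("A", "G"): MutationClass.GC_AT_TRANSITION,
    ("C", "T"): MutationClass.GC_AT_TRANSITION,
    ("T", "C"): MutationClass.GC_AT_TRANSITION,
    ("G", "T"): MutationClass.GC_TA_TRANSVERSION,
    ("T", "G"): MutationClass.GC_TA_TRANSVERSION,
    ("C", "A"): MutationClass.GC_TA_TRANSVERSION,
    ("A", "C"): MutationClass.GC_TA_TRANSVERSION,
    ("A", "T"): MutationClass.AT_TA_TRANSVERSION,
    ("T", "A"): MutationClass.AT_TA_TRANSVERSION,
    ("G", "C"): MutationClass.GC_CG_TRANSVERSION,
    ("C", "G"): MutationClass.GC_CG_TRANSVERSION,
}

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def classify_substitution(ref: str, alt: str) -> MutationClass:
    """Strand-symmetric mutation class of one ordered substitution."""
    key = (ref.upper(), alt.upper())
    if key[0] == key[1]:
        raise ValueError("ref and alt are identical")
    try:
        return _CLASS_OF_PAIR[key]
    except KeyError:
        raise ValueError(f"non-DNA substitution {ref}>{alt}") from None


@dataclass
class SpectrumSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    ts_tv: float | None          # None when there are no transversions
    oxidative_per_sample: pd.Series

    @property
    def n_calls(self) -> int:
        return sum(self.counts.values())


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    return pd.DataFrame([{"sample_id": c.sample_id, "position": c.position,
                          "ref": c.ref, "alt": c.alt, "maf": c.maf}
                         for c in calls])


def spectrum_summary(calls) -> SpectrumSummary:
    """Class counts/fractions, Ts/Tv ratio and per-sample oxidative burden.

    Ts/Tv is the transition count over the summed transversion count; with
    zero transversions it is undefined and reported as None.
    """
    df = _calls_frame(calls)
    if df.empty:
        raise ValueError("empty call set")
    classes = [classify_substitution(r, a).value
               for r, a in zip(df["ref"], df["alt"])]
    counts = {m.value: 0 for m in MutationClass}
    for c in classes:
        counts[c] += 1
    total = len(classes)
    fractions = {k: v / total for k, v in counts.items()}
    ts = counts[MutationClass.GC_AT_TRANSITION.value]
    tv = total - ts
    ts_tv = ts / tv if tv > 0 else None
    ox_mask = pd.Series(classes, index=df.index) == MutationClass.GC_TA_TRANSVERSION.value
    oxidative = df.loc[ox_mask].groupby("sample_id").size() if "sample_id" in df \
        else pd.Series(dtype=int)
    return SpectrumSummary(counts, fractions, ts_tv, oxidative)


# ---------------------------------------------------------------------------
# Coding-effect annotation

#: scorer maps (ref_aa, alt_aa) to "Deleterious" or "Neutral"
DeleteriousnessScorer = Callable[[str, str], str]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_scorer(ref_aa: str, alt_aa: str, threshold: float = 0.0) -> str:
    """Default deleteriousness stand-in: BLOSUM62 score below `threshold`
    labels the replacement Deleterious. Not equivalent to PROVEAN."""
    return "Deleterious" if _BLOSUM62[ref_aa, alt_aa] < threshold else "Neutral"


@dataclass(frozen=True)
class EffectAnnotation:
    region: str                   # protein / tRNA / rRNA / noncoding
    gene: str | None
    codon_position: int | None    # 1..3, protein regions only
    effect: str                   # synonymous / nonsynonymous / nonsense / noncoding
    ref_aa: str | None = None
    alt_aa: str | None = None
    deleteriousness: str = "NA"


def _protein_effect(feature: Feature, position: int, ref: str, alt: str,
                    genome: Mitogenome,
                    scorer: DeleteriousnessScorer) -> EffectAnnotation:
    gene_seq = genome.sequence[feature.start - 1:feature.end]
    if feature.strand == "-":
        gene_seq = str(Seq(gene_seq).reverse_complement())
        coding_index = (feature.end - position) - feature.frame
        ref_c, alt_c = _COMPLEMENT[ref], _COMPLEMENT[alt]
    else:
        coding_index = (position - feature.start) - feature.frame
        ref_c, alt_c = ref, alt
    if coding_index < 0 or coding_index >= len(gene_seq) // 3 * 3:
        # outside the complete-codon part of the frame
        return EffectAnnotation(region="protein", gene=feature.name,
                                codon_position=None, effect="noncoding")
    codon_idx, codon_pos = divmod(coding_index, 3)
    codon = gene_seq[3 * codon_idx:3 * codon_idx + 3]
    if codon[codon_pos] != ref_c:
        raise ValueError(
            f"reference base mismatch at {position} in {feature.name}: "
            f"codon has {codon[codon_pos]}, call has {ref}")
    alt_codon = codon[:codon_pos] + alt_c + codon[codon_pos + 1:]
    ref_aa = str(Seq(codon).translate(table=VERTEBRATE_MITO_TABLE))
    alt_aa = str(Seq(alt_codon).translate(table=VERTEBRATE_MITO_TABLE))
    if alt_aa == ref_aa:
        effect, deleterious = "synonymous", "NA"
    elif alt_aa == "*":
        effect, deleterious = "nonsense", "NA"
    elif ref_aa == "*":
        effect, deleterious = "nonsense", "NA"
    else:
        effect = "nonsynonymous"
        deleterious = scorer(ref_aa, alt_aa)
    return EffectAnnotation(region="protein", gene=feature.name,
                            codon_position=codon_pos + 1, effect=effect,
                            ref_aa=ref_aa, alt_aa=alt_aa,
                            deleteriousness=deleterious)


def annotate_effect(
    position: int,
    ref: str,
    alt: str,
    genome: Mitogenome,
    scorer: DeleteriousnessScorer = blosum62_scorer,
) -> list[EffectAnnotation]:
    """Annotate the coding effect of one substitution.

    Returns one record per containing gene feature (overlapping protein
    genes each get a record); positions in no gene feature, or in
    noncoding features only, yield a single `noncoding` record.
    """
    if not 1 <= position <= len(genome):
        raise ValueError(f"position {position} outside 1..{len(genome)}")
    if genome.base(position) != ref.upper():
        raise ValueError(f"reference base at {position} is {genome.base(position)}, "
                         f"call says {ref}")
    classify_substitution(ref, alt)  # validates the bases

    out: list[EffectAnnotation] = []
    for feature in genome.features_at(position, include_masks=False):
        if feature.ftype == "protein":
            out.append(_protein_effect(feature, position, ref.upper(), alt.upper(),
                                       genome, scorer))
        elif feature.ftype in ("tRNA", "rRNA"):
            out.append(EffectAnnotation(region=feature.ftype, gene=feature.name,
                                        codon_position=None, effect="noncoding"))
        else:
            out.append(EffectAnnotation(region="noncoding", gene=feature.name,
                                        codon_position=None, effect="noncoding"))
    if not out:
        out.append(EffectAnnotation(region="noncoding", gene=None,
                                    codon_position=None, effect="noncoding"))
    return out


# ---------------------------------------------------------------------------
# Spectrum and enrichment tests


def spectrum_test(
    mafs_a: Sequence[float],
    mafs_b: Sequence[float],
    test: str = "ks",
) -> tuple[float, float]:
    """Two-sided comparison of two frequency spectra.

    ``test="ks"`` runs the two-sample Kolmogorov-Smirnov test (each group
    needs >= 2 values); ``test="mwu"`` the Mann-Whitney U test (exact for
    small tie-free samples, as scipy decides).
    """
    a, b = np.asarray(mafs_a, float), np.asarray(mafs_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "ks":
        if a.size < 2 or b.size < 2:
            raise ValueError("KS test needs at least 2 values per group")
        res = stats.ks_2samp(a, b, alternative="two-sided")
    elif test == "mwu":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class EnrichmentResult:
    chi2: float
    p_value: float
    enriched: bool
    table: tuple[tuple[int, int], tuple[int, int]]


def enrichment_test(
    het_sites_in_bin: int,
    bin_length: int,
    total_het_sites: int,
    assayable_length: int,
    critical_value: float = CHI2_CRIT_P05,
    yates_correction: bool = False,
) -> EnrichmentResult:
    """Pearson chi-square enrichment of heteroplasmic sites in one partition.

    The 2x2 table is {heteroplasmic, homoplasmic} x {in bin, out of bin},
    with the out-of-bin side being the remaining assayable genome. The
    `enriched` flag compares the statistic to a caller-supplied df=1
    critical value (3.841 for p<0.05, 10.828 for p<0.001).
    """
    if bin_length <= 0:
        raise ValueError("zero-length bin")
    if bin_length >= assayable_length:
        raise ValueError("bin must be smaller than the assayable genome")
    if het_sites_in_bin > bin_length or total_het_sites > assayable_length:
        raise ValueError("site counts exceed interval lengths")
    if het_sites_in_bin > total_het_sites:
        raise ValueError("bin contains more heteroplasmic sites than the total")

    het_out = total_het_sites - het_sites_in_bin
    out_length = assayable_length - bin_length
    table = ((het_sites_in_bin, bin_length - het_sites_in_bin),
             (het_out, out_length - het_out))
    arr = np.array(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=yates_correction)
    return EnrichmentResult(float(chi2), float(p), bool(chi2 > critical_value), table)


# ---------------------------------------------------------------------------
# Private vs shared heteroplasmies


def most_recent_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Reduce a sample table to one row per individual: the most recent
    sample (highest year) of each individual."""
    idx = samples.groupby("individual_id")["year"].idxmax()
    return samples.loc[idx].reset_index(drop=True)


@dataclass
class SharingPartition:
    sites: pd.DataFrame          # position, n_individuals, label
    private_mafs: np.ndarray
    shared_mafs: np.ndarray

    @property
    def private_fraction(self) -> float:
        return float((self.sites["label"] == "private").mean())


def private_shared_partition(calls: pd.DataFrame) -> SharingPartition:
    """Label each heteroplasmic site private (one carrier individual) or
    shared, and split the MAF spectra accordingly.

    `calls` must carry ``individual_id``, ``position`` and ``maf`` columns,
    with one record per individual per site (apply
    :func:`most_recent_samples` reduction upstream for recaptures).
    """
    if calls.empty:
        return SharingPartition(pd.DataFrame(columns=["position", "n_individuals",
                                                      "label"]),
                                np.array([]), np.array([]))
    carriers = (calls.groupby("position")["individual_id"].nunique()
                .rename("n_individuals").reset_index())
    carriers["label"] = np.where(carriers["n_individuals"] == 1, "private", "shared")
    merged = calls.merge(carriers[["position", "label"]], on="position")
    return SharingPartition(
        carriers,
        merged.loc[merged["label"] == "private", "maf"].to_numpy(),
        merged.loc[merged["label"] == "shared", "maf"].to_numpy(),
    )


def annotate_calls(
    calls: pd.DataFrame,
    genome: Mitogenome,
    scorer: DeleteriousnessScorer = blosum62_scorer,
) -> pd.DataFrame:
    """Add mutation class and coding-effect columns to a call table.

    Positions inside two protein features emit one row per feature.
    """
    rows = []
    for _, call in calls.iterrows():
        base = call.to_dict()
        base["mutation_class"] = classify_substitution(call["ref"], call["alt"]).value
        for ann in annotate_effect(int(call["position"]), call["ref"], call["alt"],
                                   genome, scorer):
            rows.append({**base, "region": ann.region, "gene": ann.gene,
                         "codon_position": ann.codon_position, "effect": ann.effect,
                         "deleteriousness": ann.deleteriousness})
    return pd.DataFrame(rows)
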