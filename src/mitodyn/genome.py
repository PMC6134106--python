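"""Synthetic circular mitogenome construction and FASTA / feature-table I/O.

A vertebrate mitogenome is a ~16.5 kb circular chromosome carrying 13
protein-coding genes, 22 tRNAs, 2 rRNAs and a non-coding control region.
:func:`generate_mitogenome` builds a random sequence with a gene map of that
shape, plus primer-binding sites and repeat masks, which downstream modules
use for planting variants, masking filters and coding-effect annotation.

Coordinates are 1-based inclusive everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

FEATURE_TYPES = frozenset({"protein", "tRNA", "rRNA", "noncoding", "primer", "repeat"})
#: feature types that never carry coding information and may overlap genes
MASK_TYPES = frozenset({"primer", "repeat"})

PROTEIN_GENES = (
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
)
TRNA_GENES = (
    "trnF", "trnV", "trnL1", "trnI", "trnQ", "trnM", "trnW", "trnA",
    "trnN", "trnC", "trnY", "trnS1", "trnD", "trnK", "trnG", "trnR",
    "trnH", "trnS2", "trnL2", "trnE", "trnT", "trnP",
)
RRNA_GENES = ("rrnS", "rrnL")
# light-strand encoded features in the typical vertebrate arrangement
MINUS_STRAND = frozenset({"ND6", "trnQ", "trnA", "trnN", "trnC", "trnY",
                          "trnS2", "trnE", "trnP"})


@dataclass(frozen=True)
class Feature:
    """One annotated interval, 1-based inclusive."""

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval {self.start}..{self.end} for {self.name}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class AnnotationSpec:
    """Target composition of a synthetic mitogenome annotation.

    Fractions are of total genome length and must sum to <= 1; the
    remainder is intergenic spacer. Primer and repeat masks are placed on
    top of the gene map and may overlap any feature.
    """

    n_protein: int = 13
    protein_fraction: float = 0.66
    n_trna: int = 22
    trna_fraction: float = 0.09
    n_rrna: int = 2
    rrna_fraction: float = 0.155
    control_fraction: float = 0.06
    n_primer: int = 2
    primer_length: int = 25
    n_repeat: int = 2
    repeat_length: int = 120

    @property
    def gene_fraction_total(self) -> float:
        return (self.protein_fraction + self.trna_fraction
                + self.rrna_fraction + self.control_fraction)


@dataclass
class Mitogenome:
    """A circular DNA sequence with its feature annotation."""

    sequence: str
    features: list[Feature] = field(default_factory=list)
    name: str = "mitogenome"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValueError(f"non-ACGT symbols in sequence: {sorted(bad)}")
        L = len(self.sequence)
        for f in self.features:
            if f.end > L:
                raise ValueError(f"feature {f.name} exceeds genome length {L}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]

    def features_at(self, position: int, include_masks: bool = True) -> list[Feature]:
        return [f for f in self.features
                if f.contains(position)
                and (include_masks or f.ftype not in MASK_TYPES)]

    def masked_regions(self) -> list[tuple[int, int]]:
        """Primer and repeat intervals, for the post-call mask filter."""
        return [(f.start, f.end) for f in self.features if f.ftype in MASK_TYPES]


def _partition_lengths(total: int, n: int, multiple: int, rng: np.random.Generator) -> list[int]:
    """Split `total` into n randomly perturbed lengths, each a positive multiple."""
    if n <= 0:
        return []
    weights = rng.dirichlet(np.full(n, 8.0))
    lens = [max(multiple, int(w * total) // multiple * multiple) for w in weights]
    return lens


def generate_mitogenome(
    length: int = 16211,
    seed: int | None = None,
    annotation_spec: AnnotationSpec | None = None,
    pad: int = 500,
    name: str = "mitogenome",
) -> Mitogenome:
    """Generate a random circular mitogenome with a synthetic annotation.

    Parameters
    ----------
    length:
        Genome length in bp. Must be at least ``2 * pad`` so that the
        circular extension used by the caller is well defined.
    seed:
        Seed for :class:`numpy.random.default_rng`; identical seeds give
        byte-identical genomes.
    annotation_spec:
        Target annotation composition; defaults emulate the standard
        vertebrate gene content scaled to `length`.
    pad:
        Circular-extension pad the genome must accommodate (bp).
    """
    spec = annotation_spec or AnnotationSpec()
    if length < 2 * pad:
        raise ValueError(f"length {length} smaller than 2*pad = {2 * pad}")
    if spec.gene_fraction_total > 1.0 + 1e-9:
        raise ValueError("annotation fractions sum to more than 1")
    rng = np.random.default_rng(seed)

    protein_lens = _partition_lengths(int(spec.protein_fraction * length), spec.n_protein, 3, rng)
    trna_len = max(1, int(spec.trna_fraction * length) // max(spec.n_trna, 1))
    trna_lens = [trna_len] * spec.n_trna
    rrna_lens = _partition_lengths(int(spec.rrna_fraction * length), spec.n_rrna, 1, rng)
    control_len = int(spec.control_fraction * length)

    blocks: list[tuple[str, str, int]] = []  # (name, type, length)
    blocks += [(PROTEIN_GENES[i % len(PROTEIN_GENES)] if i < len(PROTEIN_GENES)
                else f"ORF{i + 1}", "protein", protein_lens[i])
               for i in range(spec.n_protein)]
    blocks += [(TRNA_GENES[i % len(TRNA_GENES)] if i < len(TRNA_GENES)
                else f"trnX{i + 1}", "tRNA", trna_lens[i])
               for i in range(spec.n_trna)]
    blocks += [(RRNA_GENES[i % len(RRNA_GENES)] if i < len(RRNA_GENES)
                else f"rrnX{i + 1}", "rRNA", rrna_lens[i])
               for i in range(spec.n_rrna)]
    total_genic = sum(b[2] for b in blocks) + control_len
    if total_genic > length:
        raise ValueError(
            f"length {length} too small for requested features ({total_genic} bp of annotation)")

    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]
    blocks.append(("CR", "noncoding", control_len))

    # distribute leftover bp as intergenic gaps
    leftover = length - total_genic
    gaps = rng.multinomial(leftover, np.full(len(blocks), 1.0 / len(blocks)))

    features: list[Feature] = []
    cursor = 1
    control_interval: tuple[int, int] | None = None
    for (gname, gtype, glen), gap in zip(blocks, gaps):
        cursor += int(gap)
        if glen <= 0:
            continue
        strand = "-" if gname in MINUS_STRAND else "+"
        features.append(Feature(gname, gtype, cursor, cursor + glen - 1, strand, 0))
        if gtype == "noncoding":
            control_interval = (cursor, cursor + glen - 1)
        cursor += glen

    # primer sites and repeat masks; these may overlap genes
    for i in range(spec.n_primer):
        if spec.primer_length >= length:
            break
        start = int(rng.integers(1, length - spec.primer_length + 1))
        features.append(Feature(f"primer{i + 1}", "primer",
                                start, start + spec.primer_length - 1))
    for i in range(spec.n_repeat):
        rlen = spec.repeat_length
        if rlen >= length:
            break
        if control_interval and control_interval[1] - control_interval[0] + 1 >= 2 * rlen:
            lo, hi = control_interval
            start = int(rng.integers(lo, hi - rlen + 2))
        else:
            start = int(rng.integers(1, length - rlen + 1))
        features.append(Feature(f"repeat{i + 1}", "repeat", start, start + rlen - 1))

    sequence = "".join(rng.choice(list(BASES), size=length))
    return Mitogenome(sequence, features, name=name)


# ---------------------------------------------------------------------------
# I/O: FASTA for the sequence, 6-column TSV (1-based inclusive) for features

FEATURE_COLUMNS = ["name", "type", "start", "end", "strand", "frame"]


def write_genome(genome: Mitogenome, fasta_path: str, features_path: str | None = None) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([record], fasta_path, "fasta")
    if features_path is not None:
        write_features(genome.features, features_path)


def write_features(features: list[Feature], path: str) -> None:
    df = pd.DataFrame(
        [(f.name, f.ftype, f.start, f.end, f.strand, f.frame) for f in features],
        columns=FEATURE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_features(path: str) -> list[Feature]:
    df = pd.read_csv(path, sep="\t")
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature columns {sorted(missing)}")
    return [Feature(str(r["name"]), str(r["type"]), int(r["start"]), int(r["end"]),
                    str(r["strand"]), int(r["frame"]))
            for _, r in df.iterrows()]


def read_genome(fasta_path: str, features_path: str | None = None) -> Mitogenome:
    record = next(SeqIO.parse(fasta_path, "fasta"))
    features = read_features(features_path) if features_path else []
    return Mitogenome(str(record.seq).upper(), features, name=record.id)
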