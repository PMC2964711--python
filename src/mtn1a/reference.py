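"""Reference mitogenome coordinates, windows and the packaged reference sequence.

All positions in this package are 1-based coordinates on a 16,569-nt circular
human mitochondrial genome laid out like the revised Cambridge Reference
Sequence (rCRS): control region spanning 16024..16569 + 1..576, coding region
577..16023, with the canonical gene map of the 13 protein-coding genes, 2
rRNAs and 22 tRNAs.

The packaged FASTA (``data/synthetic_rcrs.fasta``) is a *synthetic* reference:
a deterministic pseudorandom sequence with rCRS-like coordinates, poly-C
tracts in both hypervariable segments, and a small set of anchored bases at
positions where the shipped haplotype fixture's transversion notation
constrains the reference state.  Analyses of real data should drop in the
true rCRS (NC_012920) via :func:`load_reference`; every coordinate convention
is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

MT_LENGTH = 16569

#: transition partners (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

# 1-based inclusive intervals; strand +1 = heavy strand, -1 = light strand.
# Canonical NC_012920 feature coordinates.
GENE_MAP: tuple[tuple[str, int, int, int, str], ...] = (
    ("TRNF", 577, 647, 1, "trna"),
    ("RNR1", 648, 1601, 1, "rrna"),
    ("TRNV", 1602, 1670, 1, "trna"),
    ("RNR2", 1671, 3229, 1, "rrna"),
    ("TRNL1", 3230, 3304, 1, "trna"),
    ("ND1", 3307, 4262, 1, "protein"),
    ("TRNI", 4263, 4331, 1, "trna"),
    ("TRNQ", 4329, 4400, -1, "trna"),
    ("TRNM", 4402, 4469, 1, "trna"),
    ("ND2", 4470, 5511, 1, "protein"),
    ("TRNW", 5512, 5579, 1, "trna"),
    ("TRNA", 5587, 5655, -1, "trna"),
    ("TRNN", 5657, 5729, -1, "trna"),
    ("TRNC", 5761, 5826, -1, "trna"),
    ("TRNY", 5826, 5891, -1, "trna"),
    ("CO1", 5904, 7445, 1, "protein"),
    ("TRNS1", 7446, 7514, -1, "trna"),
    ("TRND", 7518, 7585, 1, "trna"),
    ("CO2", 7586, 8269, 1, "protein"),
    ("TRNK", 8295, 8364, 1, "trna"),
    ("ATP8", 8366, 8572, 1, "protein"),
    ("ATP6", 8527, 9207, 1, "protein"),
    ("CO3", 9207, 9990, 1, "protein"),
    ("TRNG", 9991, 10058, 1, "trna"),
    ("ND3", 10059, 10404, 1, "protein"),
    ("TRNR", 10405, 10469, 1, "trna"),
    ("ND4L", 10470, 10766, 1, "protein"),
    ("ND4", 10760, 12137, 1, "protein"),
    ("TRNH", 12138, 12206, 1, "trna"),
    ("TRNS2", 12207, 12265, 1, "trna"),
    ("TRNL2", 12266, 12336, 1, "trna"),
    ("ND5", 12337, 14148, 1, "protein"),
    ("ND6", 14149, 14673, -1, "protein"),
    ("TRNE", 14674, 14742, -1, "trna"),
    ("CYB", 14747, 15887, 1, "protein"),
    ("TRNT", 15888, 15953, 1, "trna"),
    ("TRNP", 15956, 16023, -1, "trna"),
)

# Bases fixed in the synthetic reference.  These are the positions at which
# the shipped haplotype fixture's base-suffixed (transversion) tokens, or the
# poly-C tract layout, constrain the reference state.
_ANCHORS = {
    73: "A",
    185: "G",
    263: "A",
    16114: "C",
    16147: "C",
    16183: "A",
    16187: "C",
    16189: "T",
    16519: "T",
}

_POLYC_HVS2 = (303, 315)   # CCCCCCC T CCCCC with T at 310
_POLYC_HVS1 = (16184, 16193)


class ReferenceError(ValueError):
    """Raised for malformed reference input."""


@dataclass(frozen=True)
class ReferenceAnnotation:
    """The reference sequence plus the coordinate conventions used throughout.

    ``excluded_sites`` are never scored by the variant caller (16519 by
    default).  ``polyc_tracts`` are hypervariable homopolymer tracts in which
    *length variation* (insertions/deletions) is never scored; substitutions
    inside the tracts are kept, because diagnostic sites such as 16189 fall
    within them.
    """

    sequence: str
    excluded_sites: frozenset[int] = frozenset({16519})
    polyc_tracts: tuple[tuple[int, int], ...] = (_POLYC_HVS1, _POLYC_HVS2)
    hvs1_window: tuple[int, int] = (16024, 16383)
    hvs2_window: tuple[int, int] = (57, 372)
    coding_window: tuple[int, int] = (577, 16023)
    #: parse bounds: tokens of each segment are accepted anywhere in the
    #: control region half they name (published tables use e.g. 16463)
    hvs1_parse_window: tuple[int, int] = (16024, 16569)
    hvs2_parse_window: tuple[int, int] = (1, 576)

    def __post_init__(self) -> None:
        if len(self.sequence) != MT_LENGTH:
            raise ReferenceError(
                f"reference must be {MT_LENGTH} nt, got {len(self.sequence)}"
            )
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ReferenceError(f"non-nucleotide characters in reference: {bad}")

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= MT_LENGTH:
            raise ReferenceError(f"position {position} outside [1, {MT_LENGTH}]")
        return self.sequence[position - 1]

    def in_polyc(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.polyc_tracts)

    def in_window(self, position: int, window: tuple[int, int]) -> bool:
        return window[0] <= position <= window[1]

    def features_at(self, position: int) -> list[tuple[str, int, int, int, str]]:
        return [f for f in GENE_MAP if f[1] <= position <= f[2]]

    def control_sites(self) -> list[int]:
        """Control-region positions legal for scoring substitutions.

        Excludes ``excluded_sites`` and (conservatively) the poly-C tracts,
        which is also the site pool the simulator plants control mutations in.
        """
        sites = []
        for lo, hi in (self.hvs1_window, self.hvs2_window):
            for p in range(lo, hi + 1):
                if p in self.excluded_sites or self.in_polyc(p):
                    continue
                sites.append(p)
        return sites


def build_synthetic_reference(seed: int = 16569) -> str:
    """Deterministically generate the synthetic 16,569-nt reference sequence.

    Pseudorandom bases at human-mtDNA-like composition, overlaid with the
    poly-C tracts (with the canonical interrupting T at 310 / 16189) and the
    anchored bases listed in ``_ANCHORS``.  The packaged FASTA fixture is the
    output of this function; a test asserts they stay identical.
    """
    rng = np.random.default_rng(seed)
    # approximate base composition of the human mitogenome heavy strand
    bases = rng.choice(list("ACGT"), size=MT_LENGTH, p=[0.31, 0.31, 0.13, 0.25])
    seq = bases.copy()
    for lo, hi in (_POLYC_HVS2, _POLYC_HVS1):
        for p in range(lo, hi + 1):
            seq[p - 1] = "C"
    seq[310 - 1] = "T"  # canonical interruption of the HVS-II tract
    for pos, b in _ANCHORS.items():
        seq[pos - 1] = b
    return "".join(seq)


def load_reference(path=None) -> ReferenceAnnotation:
    """Load a reference FASTA (default: the packaged synthetic reference)."""
    if path is None:
        with resources.as_file(
            resources.files("mtn1a.data") / "synthetic_rcrs.fasta"
        ) as p:
            record = next(SeqIO.parse(str(p), "fasta"))
    else:
        record = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceAnnotation(sequence=str(record.seq).upper())


def translate_codon(codon: str) -> str:
    """Translate a codon under the vertebrate mitochondrial code."""
    return str(Seq(codon).translate(table=2))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def synonymous_transition_sites(ref: ReferenceAnnotation) -> list[int]:
    """Exact enumeration of coding positions whose transition is synonymous.

    A position qualifies if it lies in at least one protein-coding gene and
    the transition substitution leaves the encoded amino acid unchanged in
    *every* protein-coding gene overlapping the position.
    """
    from .dating import MutationClassifier  # local import to avoid a cycle

    mc = MutationClassifier(ref)
    out = []
    lo, hi = ref.coding_window
    for pos in range(lo, hi + 1):
        feats = [f for f in ref.features_at(pos) if f[4] == "protein"]
        if not feats:
            continue
        if mc.is_synonymous(pos, TRANSITION_PARTNER[ref.base(pos)]):
            out.append(pos)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
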