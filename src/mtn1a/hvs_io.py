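"""Mutation-motif nomenclature, haplotype tables and variant calling.

The motif dialect is the one used throughout the mtDNA phylogeography
literature: a hyphen-separated list of per-site tokens scored against the
reference, HVS-I positions written "minus 16000" (``147A`` means a C>A
transversion at 16147), a bare number meaning a transition, a base suffix a
transversion (or an explicitly stated derived base), ``d`` a deletion,
``iX``/``+X`` an insertion of X after the site, and an ``@`` prefix a back
mutation (reversion to the reference state).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .reference import (
    MT_LENGTH,
    TRANSITION_PARTNER,
    ReferenceAnnotation,
)


class MotifParseError(ValueError):
    """A motif token could not be parsed."""


class PositionRangeError(ValueError):
    """A call lies outside the segment it was declared in."""


class SchemaError(ValueError):
    """A haplotype table is missing mandatory columns."""


class AlphabetError(ValueError):
    """A sequence contains non-nucleotide characters."""


SEGMENTS = ("hvs1", "hvs2", "coding")

_TOKEN_RE = re.compile(
    r"^(?P<back>@?)(?P<pos>\d+)(?P<suffix>d|i[ACGT]+|\+[ACGT]+|[ACGT])?$",
    re.IGNORECASE,
)


@dataclass(frozen=True, order=True)
class MutationCall:
    """One scored difference against the reference.

    ``derived`` holds the new base for substitutions, the inserted string for
    insertions, and is empty for deletions.  ``is_back_mutation`` marks the
    ``@``-prefixed reversion to the reference state.
    """

    position: int
    ref_base: str
    event: str  # transition | transversion | deletion | insertion
    derived: str = ""
    is_back_mutation: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise PositionRangeError(
                f"position {self.position} outside [1, {MT_LENGTH}]"
            )
        if self.event == "transition":
            if self.derived != TRANSITION_PARTNER[self.ref_base]:
                raise MotifParseError(
                    f"{self.position}: {self.ref_base}>{self.derived} is not a transition"
                )
        elif self.event == "transversion":
            if self.derived in ("", self.ref_base, TRANSITION_PARTNER[self.ref_base]):
                raise MotifParseError(
                    f"{self.position}: {self.ref_base}>{self.derived} is not a transversion"
                )
        elif self.event == "insertion":
            if not self.derived:
                raise MotifParseError(f"{self.position}: empty insertion")
        elif self.event == "deletion":
            if self.derived:
                raise MotifParseError(f"{self.position}: deletion carries derived state")
        else:
            raise MotifParseError(f"unknown event {self.event!r}")

    @property
    def is_indel(self) -> bool:
        return self.event in ("deletion", "insertion")


def _segment_window(segment: str, ref: ReferenceAnnotation) -> tuple[int, int]:
    if segment == "hvs1":
        return ref.hvs1_parse_window
    if segment == "hvs2":
        return ref.hvs2_parse_window
    if segment == "coding":
        return ref.coding_window
    raise ValueError(f"unknown segment {segment!r}; expected one of {SEGMENTS}")


def parse_token(token: str, segment: str, ref: ReferenceAnnotation) -> MutationCall:
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise MotifParseError(f"cannot parse motif token {token!r}")
    pos = int(m.group("pos"))
    if segment == "hvs1" and pos < 16000:
        pos += 16000
    lo, hi = _segment_window(segment, ref)
    if not lo <= pos <= hi:
        raise PositionRangeError(
            f"token {token!r}: position {pos} outside {segment} window [{lo}, {hi}]"
        )
    back = bool(m.group("back"))
    suffix = (m.group("suffix") or "").upper()
    ref_base = ref.base(pos)
    if suffix == "":
        return MutationCall(pos, ref_base, "transition",
                            TRANSITION_PARTNER[ref_base], back)
    if suffix == "D":
        return MutationCall(pos, ref_base, "deletion", "", back)
    if suffix.startswith(("I", "+")):
        return MutationCall(pos, ref_base, "insertion", suffix[1:], back)
    # explicit derived base: transition partner stays a transition
    event = "transition" if suffix == TRANSITION_PARTNER[ref_base] else "transversion"
    return MutationCall(pos, ref_base, event, suffix, back)


def parse_motif(motif: str, segment: str, ref: ReferenceAnnotation) -> list[MutationCall]:
    """Parse a hyphen-separated motif into calls (sorted by position)."""
    motif = (motif or "").strip()
    if not motif:
        return []
    calls = [parse_token(t, segment, ref) for t in motif.split("-") if t.strip()]
    return sorted(calls, key=_sort_key)


def _sort_key(c: MutationCall):
    # insertions after the substitution at the same site, as printed in tables
    return (c.position, c.event == "insertion", c.derived)


def format_token(call: MutationCall, segment: str) -> str:
    pos = call.position - 16000 if segment == "hvs1" else call.position
    back = "@" if call.is_back_mutation else ""
    if call.event == "deletion":
        return f"{back}{pos}d"
    if call.event == "insertion":
        return f"{back}{pos}i{call.derived}"
    if call.event == "transition":
        return f"{back}{pos}"
    return f"{back}{pos}{call.derived}"


def format_motif(calls: list[MutationCall], segment: str,
                 ref: ReferenceAnnotation | None = None) -> str:
    """Inverse of :func:`parse_motif`; tokens sorted by position."""
    if ref is not None:
        lo, hi = _segment_window(segment, ref)
        for c in calls:
            if not lo <= c.position <= hi:
                raise PositionRangeError(
                    f"call at {c.position} outside {segment} window [{lo}, {hi}]"
                )
    return "-".join(format_token(c, segment) for c in sorted(calls, key=_sort_key))


#: HVS-II calls implicit in published tables ("73, 263 in addition")
IMPLICIT_HVS2 = (73, 263)


@dataclass
class Haplotype:
    """An observed record: control-region calls plus sampling metadata."""

    id: str
    hvs1: list[MutationCall]
    hvs2: list[MutationCall]
    count: int = 1
    population: str = ""
    region: str = ""
    source: str = ""
    recorded_haplogroup: str = ""
    assigned_clade: str | None = None
    hvs2_typed: bool = False
    coding: list[MutationCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"{self.id}: count must be >= 1, got {self.count}")
        for seg in ("hvs1", "hvs2"):
            calls = getattr(self, seg)
            subs = [c.position for c in calls if not c.is_indel]
            if len(subs) != len(set(subs)):
                raise ValueError(f"{self.id}: duplicate positions in {seg}")


REQUIRED_COLUMNS = (
    "haplogroup", "hvs1_motif", "hvs2_motif", "n", "population", "region", "source",
)


def read_haplotype_table(path, ref: ReferenceAnnotation) -> list[Haplotype]:
    """Read a published-style haplotype table (TSV, one row per motif/origin).

    Non-empty HVS-II motifs are augmented with the implicit 73 and 263
    transitions.  The recorded haplogroup label is kept for concordance
    checks but never trusted by the classifier.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"haplotype table missing columns: {sorted(missing)}")
    haplotypes = []
    for i, row in df.iterrows():
        try:
            n = int(row["n"])
        except ValueError as exc:
            raise ValueError(f"row {i}: count {row['n']!r} is not an integer") from exc
        if n < 1:
            raise ValueError(f"row {i}: count must be >= 1, got {n}")
        hvs1 = parse_motif(row["hvs1_motif"], "hvs1", ref)
        hvs2_typed = bool(row["hvs2_motif"].strip())
        hvs2 = parse_motif(row["hvs2_motif"], "hvs2", ref)
        if hvs2_typed:
            present = {c.position for c in hvs2}
            for pos in IMPLICIT_HVS2:
                if pos not in present:
                    hvs2.append(parse_token(str(pos), "hvs2", ref))
            hvs2.sort(key=_sort_key)
        haplotypes.append(
            Haplotype(
                id=f"H{i + 1:03d}",
                hvs1=hvs1,
                hvs2=hvs2,
                hvs2_typed=hvs2_typed,
                count=n,
                population=row["population"],
                region=row["region"],
                source=row["source"],
                recorded_haplogroup=row["haplogroup"],
            )
        )
    return haplotypes


def load_fixture_table(ref: ReferenceAnnotation | None = None) -> list[Haplotype]:
    """The packaged survey of published N1a control-region haplotypes."""
    from importlib import resources
    from .reference import load_reference

    if ref is None:
        ref = load_reference()
    with resources.as_file(
        resources.files("mtn1a.data") / "n1a_haplotypes.tsv"
    ) as p:
        return read_haplotype_table(p, ref)


# ---------------------------------------------------------------------------
# variant calling against the reference


def _check_alphabet(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise AlphabetError(f"non-nucleotide characters: {sorted(bad)}")
    return seq


def _substitution_call(pos: int, ref_base: str, alt: str) -> MutationCall:
    event = "transition" if alt == TRANSITION_PARTNER[ref_base] else "transversion"
    return MutationCall(pos, ref_base, event, alt)


def call_variants(seq: str, ref: ReferenceAnnotation) -> list[MutationCall]:
    """Score a complete mitogenome against the reference.

    Equal-length sequences are compared positionally; length differences go
    through a global pairwise alignment, with indels right-shifted to the
    3' end of homopolymer runs.  Calls at excluded sites (16519) and indels
    inside the hypervariable poly-C tracts are dropped; ``N`` bases are never
    scored.
    """
    seq = _check_alphabet(seq)
    if abs(len(seq) - MT_LENGTH) > 50:
        raise ValueError(f"sequence length {len(seq)} too far from {MT_LENGTH}")
    if len(seq) == MT_LENGTH:
        a = np.frombuffer(seq.encode(), dtype="S1")
        b = np.frombuffer(ref.sequence.encode(), dtype="S1")
        diff = np.nonzero((a != b) & (a != b"N"))[0]
        calls = [
            _substitution_call(int(i) + 1, ref.sequence[i], seq[i]) for i in diff
        ]
    else:
        calls = _align_and_call(seq, ref)
    return [
        c
        for c in calls
        if c.position not in ref.excluded_sites
        and not (c.is_indel and ref.in_polyc(c.position))
    ]


def _align_and_call(seq: str, ref: ReferenceAnnotation) -> list[MutationCall]:
    import edlib

    result = edlib.align(seq, ref.sequence, mode="NW", task="path")
    ref_aln, seq_aln = [], []
    rpos_ = spos_ = 0
    for n, op in _cigar_ops(result["cigar"]):
        if op in ("=", "X", "M"):
            ref_aln.append(ref.sequence[rpos_: rpos_ + n])
            seq_aln.append(seq[spos_: spos_ + n])
            rpos_ += n
            spos_ += n
        elif op == "D":  # gap in query: deletion relative to the reference?
            # edlib 'D' consumes the target (reference) only
            ref_aln.append(ref.sequence[rpos_: rpos_ + n])
            seq_aln.append("-" * n)
            rpos_ += n
        elif op == "I":  # consumes the query only
            ref_aln.append("-" * n)
            seq_aln.append(seq[spos_: spos_ + n])
            spos_ += n
    ref_aln, seq_aln = "".join(ref_aln), "".join(seq_aln)
    calls: list[MutationCall] = []
    rpos = 0  # 1-based position of the last consumed reference base
    i = 0
    while i < len(ref_aln):
        r, s = ref_aln[i], seq_aln[i]
        if r != "-" and s != "-":
            rpos += 1
            if r != s and s != "N":
                calls.append(_substitution_call(rpos, r, s))
            i += 1
        elif s == "-":  # deletion run
            start = rpos + 1
            run = ""
            while i < len(ref_aln) and seq_aln[i] == "-":
                run += ref_aln[i]
                rpos += 1
                i += 1
            first = _shift_deletion(start, run, ref)
            for k in range(len(run)):
                calls.append(MutationCall(first + k, ref.base(first + k), "deletion"))
        else:  # insertion run (r == '-')
            run = ""
            while i < len(ref_aln) and ref_aln[i] == "-":
                run += seq_aln[i]
                i += 1
            pos, run = _shift_insertion(rpos, run, ref)
            calls.append(MutationCall(pos, ref.base(pos), "insertion", run))
    return sorted(calls, key=_sort_key)


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _shift_deletion(start: int, run: str, ref: ReferenceAnnotation) -> int:
    """Right-shift a deleted block to the 3' end of a homopolymer run."""
    end = start + len(run) - 1
    while end + 1 <= MT_LENGTH and ref.base(end + 1) == ref.base(start):
        start += 1
        end += 1
    return start


def _shift_insertion(after: int, run: str, ref: ReferenceAnnotation) -> tuple[int, str]:
    """Right-shift an inserted block through matching reference bases."""
    while after + 1 <= MT_LENGTH and ref.base(after + 1) == run[0]:
        after += 1
        run = run[1:] + run[0]
    return max(after, 1), run


def apply_mutations(seq: str, calls: list[MutationCall]) -> str:
    """Apply calls to a sequence (substitutions, indels, back mutations)."""
    out = list(seq)
    # apply from the highest coordinate down so indels do not shift others
    for c in sorted(calls, key=_sort_key, reverse=True):
        i = c.position - 1
        if c.is_back_mutation:
            out[i] = c.ref_base
        elif c.event == "deletion":
            del out[i]
        elif c.event == "insertion":
            out[i + 1 : i + 1] = list(c.derived)
        else:
            out[i] = c.derived
    return "".join(out)
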