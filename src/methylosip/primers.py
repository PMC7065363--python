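"""Degenerate PCR primer design from a DNA multiple alignment.

The procedure used for the divergent methanol-dehydrogenase gene mdh2:
profile an alignment of reference genes for column-level conservation,
exhaustively enumerate every 18-20 nt window containing at most three
non-conserved columns (and no indels), encode each window as a minimal
degenerate IUPAC consensus, and screen candidate primer pairs in silico
against positive- and negative-control templates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlignmentMatrix",
    "ScanParameters",
    "WindowCandidate",
    "AmpliconPrediction",
    "conservation_profile",
    "scan_conserved_windows",
    "consensus_primer",
    "rank_windows",
    "predict_amplicons",
    "reverse_complement",
    "iupac_code",
]

ALLOWED_CHARS = frozenset("ACGTN-")
BASES = frozenset("ACGT")

# minimal IUPAC code for each non-empty subset of {A,C,G,T}
_SET_TO_CODE = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
CODE_TO_SET: Mapping[str, frozenset[str]] = {v: k for k, v in _SET_TO_CODE.items()}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CODE_COMPLEMENT = {
    code: _SET_TO_CODE[frozenset(_COMPLEMENT[b] for b in bases)]
    for bases, code in _SET_TO_CODE.items()
}


def iupac_code(bases: Iterable[str]) -> str:
    """Minimal IUPAC code covering a set of bases (A/C/G/T)."""
    key = frozenset(b.upper() for b in bases)
    if not key <= BASES or not key:
        raise ValueError(f"not a set of DNA bases: {sorted(key)}")
    return _SET_TO_CODE[key]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) DNA string."""
    try:
        return "".join(_CODE_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r}") from None


class AlignmentMatrix:
    """A DNA multiple alignment as a character matrix.

    Rows are sequences, columns alignment positions; characters are restricted
    to A, C, G, T, N and the gap '-'.  Input case is folded to upper.
    """

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if len(rows) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        rows = [r.upper() for r in rows]
        bad = set("".join(rows)) - ALLOWED_CHARS
        if bad:
            raise ValueError(f"disallowed alignment characters: {sorted(bad)}")
        self.ids = list(ids)
        self.matrix = np.array([list(r) for r in rows], dtype="<U1")

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def column(self, j: int) -> set[str]:
        return set(self.matrix[:, j])

    def row(self, i: int) -> str:
        return "".join(self.matrix[i])

    @classmethod
    def from_records(cls, records) -> "AlignmentMatrix":
        """Build from Bio.SeqRecord iterables (e.g. Bio.AlignIO output)."""
        recs = list(records)
        return cls([r.id for r in recs], [str(r.seq) for r in recs])


@dataclass(frozen=True)
class ScanParameters:
    """Window-scan settings: primer length range and variability budget."""

    min_len: int = 18
    max_len: int = 20
    max_nonconserved: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")
        if self.max_nonconserved < 0:
            raise ValueError("max_nonconserved must be >= 0")


@dataclass(frozen=True)
class WindowCandidate:
    """A candidate primer region: 0-based half-open window [start, start+length)."""

    start: int
    length: int
    nonconserved_count: int
    consensus: str
    degeneracy: int


@dataclass(frozen=True)
class AmpliconPrediction:
    """One predicted PCR product on a template."""

    template_id: str
    forward_position: int
    reverse_position: int
    product_length: int
    total_mismatches: int


def conservation_profile(alignment: AlignmentMatrix) -> np.ndarray:
    """Boolean flag per column: True iff all rows share one base in {A,C,G,T}.

    Any gap or N anywhere in a column makes it non-conserved.
    """
    flags = np.empty(alignment.n_cols, dtype=bool)
    for j in range(alignment.n_cols):
        col = alignment.column(j)
        flags[j] = len(col) == 1 and col <= BASES
    return flags


def _column_classes(alignment: AlignmentMatrix) -> np.ndarray:
    """Per-column class: 0 conserved, 1 variable (>=2 plain bases), 2 disqualified.

    Gap or ambiguity characters disqualify a column from appearing in any
    primer window (primers cannot span indels).
    """
    classes = np.empty(alignment.n_cols, dtype=int)
    for j in range(alignment.n_cols):
        col = alignment.column(j)
        if not col <= BASES:
            classes[j] = 2
        elif len(col) == 1:
            classes[j] = 0
        else:
            classes[j] = 1
    return classes


def scan_conserved_windows(
    alignment: AlignmentMatrix, params: ScanParameters = ScanParameters()
) -> list[WindowCandidate]:
    """Enumerate all windows of length min_len..max_len with a bounded number
    of non-conserved columns and no gap/ambiguity columns, ordered by
    (start, length)."""
    if alignment.n_cols < params.min_len:
        warnings.warn(
            f"alignment ({alignment.n_cols} columns) shorter than min_len "
            f"{params.min_len}; no windows",
            stacklevel=2,
        )
        return []
    classes = _column_classes(alignment)
    variable = np.cumsum(np.concatenate([[0], classes == 1]))
    disqualified = np.cumsum(np.concatenate([[0], classes == 2]))
    out: list[WindowCandidate] = []
    for start in range(alignment.n_cols - params.min_len + 1):
        for length in range(params.min_len, params.max_len + 1):
            end = start + length
            if end > alignment.n_cols:
                break
            if disqualified[end] - disqualified[start]:
                continue
            n_var = int(variable[end] - variable[start])
            if n_var > params.max_nonconserved:
                continue
            consensus, degeneracy = consensus_primer(alignment, start, length)
            out.append(WindowCandidate(start, length, n_var, consensus, degeneracy))
    return out


def rank_windows(windows: Iterable[WindowCandidate]) -> list[WindowCandidate]:
    """Convenience sort: fewest variable columns, then lowest degeneracy,
    then longest, then leftmost."""
    return sorted(windows, key=lambda w: (w.nonconserved_count, w.degeneracy, -w.length, w.start))


def consensus_primer(
    alignment: AlignmentMatrix, start: int, length: int
) -> tuple[str, int]:
    """Minimal degenerate IUPAC consensus over a window, with its degeneracy.

    Degeneracy is the product over columns of the number of distinct bases
    observed; an N in a column stands for any base (contributes 4).  A gap in
    the window is an error: no primer can be synthesized across an indel.
    """
    if start < 0 or length < 1 or start + length > alignment.n_cols:
        raise ValueError(f"window [{start}, {start + length}) outside alignment")
    codes = []
    degeneracy = 1
    for j in range(start, start + length):
        col = alignment.column(j)
        if "-" in col:
            raise ValueError(f"gap in consensus window at column {j}")
        if "N" in col:
            col = set(BASES)
        codes.append(iupac_code(col))
        degeneracy *= len(CODE_TO_SET[codes[-1]])
    return "".join(codes), degeneracy


def _validate_primer(primer: str) -> str:
    primer = primer.upper()
    bad = set(primer) - set(CODE_TO_SET)
    if not primer or bad:
        raise ValueError(f"invalid IUPAC primer {primer!r}: {sorted(bad)}")
    return primer


def _match_sites(
    primer: str, template: str, max_mismatches: int, three_prime_is_start: bool
) -> list[tuple[int, int]]:
    """(position, mismatches) for every site where the primer-derived string
    anneals with <= max_mismatches and a perfect 3'-terminal 3 bases.

    `template`-strand string of the primer is passed in; for a forward primer
    the 3' end is its last 3 characters, for a reverse primer (already
    reverse-complemented onto the top strand) it is the first 3.
    """
    n, m = len(template), len(primer)
    sets = [CODE_TO_SET[c] for c in primer]
    anchor = range(0, min(3, m)) if three_prime_is_start else range(max(0, m - 3), m)
    anchor = set(anchor)
    sites = []
    for pos in range(n - m + 1):
        mism = 0
        ok = True
        for i in range(m):
            base = template[pos + i]
            matched = base in sets[i]
            if not matched:
                if i in anchor:
                    ok = False
                    break
                mism += 1
                if mism > max_mismatches:
                    ok = False
                    break
        if ok:
            sites.append((pos, mism))
    return sites


def predict_amplicons(
    forward: str,
    reverse: str,
    templates: Mapping[str, str] | Sequence[tuple[str, str]],
    max_mismatches: int = 0,
    product_range: tuple[int, int] = (100, 2000),
) -> list[AmpliconPrediction]:
    """In-silico PCR: predicted products of a primer pair on plain-DNA templates.

    The forward primer is matched on the top strand, the reverse primer on the
    bottom strand (i.e. its reverse complement is matched on the top strand
    downstream of the forward site).  IUPAC codes in primers match any base
    they cover; the 3 positions at each primer's 3' end must match exactly in
    all modes, and the combined mismatch count of a site pair must not exceed
    max_mismatches.  Product length runs from the forward 5' end through the
    reverse 5' end inclusive.
    """
    forward = _validate_primer(forward)
    reverse = _validate_primer(reverse)
    rev_site = reverse_complement(reverse)
    if not isinstance(templates, Mapping):
        templates = dict(templates)
    lo, hi = product_range
    out: list[AmpliconPrediction] = []
    for tid, seq in templates.items():
        seq = seq.upper()
        fwd_sites = _match_sites(forward, seq, max_mismatches, three_prime_is_start=False)
        rev_sites = _match_sites(rev_site, seq, max_mismatches, three_prime_is_start=True)
        for fpos, fmism in fwd_sites:
            for rpos, rmism in rev_sites:
                if rpos < fpos:
                    continue
                product = rpos + len(rev_site) - fpos
                total = fmism + rmism
                if lo <= product <= hi and total <= max_mismatches:
                    out.append(AmpliconPrediction(tid, fpos, rpos, product, total))
    return out
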