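"""In silico PCR: enumerate predicted products of a primer pair on templates.

Given a forward and a reverse primer, a product is predicted wherever the
forward primer matches one strand of a template and the reverse complement of
the reverse primer matches downstream on the same strand, within a maximum
product length.  Degenerate IUPAC codes in either primer or template match
set-wise (two codes match when their base sets intersect), so a primer ``Y``
matches a template ``C`` or ``T`` at zero mismatch cost.  Both strands are
searched; coordinates are always reported 0-based half-open on the forward
strand of the template.

This replaces a web-based in silico PCR tool for tasks such as estimating how
many copies of a repetitive element a primer pair would amplify per genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate(seq: str, what: str) -> str:
    seq = seq.upper()
    for ch in seq:
        if ch not in IUPAC_SETS:
            raise ValueError(f"non-IUPAC symbol {ch!r} in {what}")
    return seq


# 16x16 compatibility table over IUPAC codes, indexed by _CODE_INDEX.
_CODES = "ACGTURYSWKMBDHVN"
_CODE_INDEX = {c: i for i, c in enumerate(_CODES)}
_COMPAT = np.zeros((16, 16), dtype=bool)
for _a, _i in _CODE_INDEX.items():
    for _b, _j in _CODE_INDEX.items():
        _COMPAT[_i, _j] = bool(IUPAC_SETS[_a] & IUPAC_SETS[_b])


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def _match_starts(template_enc: np.ndarray, primer_enc: np.ndarray, max_mismatch: int) -> np.ndarray:
    """Start positions where primer matches template with <= max_mismatch."""
    n, m = len(template_enc), len(primer_enc)
    if n < m:
        return np.empty(0, dtype=np.intp)
    n_windows = n - m + 1
    mismatches = np.zeros(n_windows, dtype=np.int32)
    for j in range(m):
        mismatches += ~_COMPAT[primer_enc[j], template_enc[j : j + n_windows]]
    return np.flatnonzero(mismatches <= max_mismatch)


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on one template.

    ``start``/``end`` are 0-based half-open coordinates on the forward strand
    of the template regardless of ``strand``; ``strand`` is the orientation of
    the forward-primer hit.  ``sequence`` is the product in amplicon
    orientation (reverse-complemented template slice for ``-`` products).
    """

    template_id: str
    start: int
    end: int
    strand: str
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != self.length:
            raise ValueError("amplicon length inconsistent with coordinates")

    @property
    def start_1based(self) -> int:
        """1-based inclusive start, for display."""
        return self.start + 1


def find_amplicons(
    template: str,
    fwd: str,
    rev: str,
    *,
    template_id: str = "template",
    max_product_bp: int = 4000,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Enumerate predicted PCR products of (fwd, rev) on one template.

    Parameters
    ----------
    template : IUPAC DNA string.
    fwd, rev : primers, written 5'->3' as ordered for PCR.
    max_product_bp : maximum product length reported.
    max_mismatch : mismatches tolerated per primer (degenerate-code matches
        cost nothing).

    Both strands are searched; overlapping products are all reported, sorted
    by start coordinate.
    """
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    template = _validate(template, "template")
    fwd = _validate(fwd, "forward primer")
    rev = _validate(rev, "reverse primer")
    if max_product_bp < len(fwd) + len(rev):
        raise ValueError("max_product_bp shorter than the two primers")

    results: list[Amplicon] = []
    n = len(template)
    for strand, strand_template in (("+", template), ("-", reverse_complement(template))):
        enc = _encode(strand_template)
        fwd_hits = _match_starts(enc, _encode(fwd), max_mismatch)
        rev_hits = _match_starts(enc, _encode(reverse_complement(rev)), max_mismatch)
        rev_ends = rev_hits + len(rev)
        for f in fwd_hits:
            # products with a non-negative gap between the primer footprints
            lo = np.searchsorted(rev_hits, f + len(fwd))
            for e in rev_ends[lo:]:
                length = int(e - f)
                if length > max_product_bp:
                    break
                seq = strand_template[f:e]
                if strand == "+":
                    start, end = int(f), int(e)
                else:
                    start, end = n - int(e), n - int(f)
                results.append(Amplicon(template_id, start, end, strand, length, seq))
    results.sort(key=lambda a: (a.start, a.end, a.strand))
    return results


def find_amplicons_multi(
    templates: Iterable[tuple[str, str]],
    fwd: str,
    rev: str,
    *,
    max_product_bp: int = 4000,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Run ``find_amplicons`` over (id, sequence) records; sorted by (id, start)."""
    out: list[Amplicon] = []
    for rec_id, seq in templates:
        out.extend(
            find_amplicons(
                seq, fwd, rev,
                template_id=rec_id,
                max_product_bp=max_product_bp,
                max_mismatch=max_mismatch,
            )
        )
    out.sort(key=lambda a: (a.template_id, a.start, a.end, a.strand))
    return out


def copies_per_genome(
    templates: Sequence[tuple[str, str]],
    fwd: str,
    rev: str,
    *,
    max_product_bp: int = 4000,
    max_mismatch: int = 0,
) -> int:
    """Total predicted product count over a template collection.

    Intended for repeat-element copy-number estimation (run the primers over
    the records of a genome assembly); the count is the theoretical copies per
    genome the primer pair would amplify.
    """
    templates = list(templates)
    if not templates:
        raise ValueError("empty template collection")
    return len(
        find_amplicons_multi(
            templates, fwd, rev,
            max_product_bp=max_product_bp, max_mismatch=max_mismatch,
        )
    )


def restriction_site_count(template: str, site: str = "GGCC") -> tuple[int, float]:
    """Count non-overlapping occurrences of a restriction site, left-to-right.

    Returns ``(count, mean_fragment_length)`` where the expected mean fragment
    length of a digest with ``count`` cuts is ``len(template) / (count + 1)``.
    The site must be non-degenerate; only the forward strand is scanned
    (palindromic sites — the usual case — make the reverse scan redundant).
    """
    if not site:
        raise ValueError("empty restriction site")
    site = _validate(site, "site")
    if any(len(IUPAC_SETS[c]) != 1 for c in site):
        raise ValueError("restriction site must be non-degenerate")
    template = _validate(template, "template")
    count = template.count(site)  # str.count is non-overlapping, left-to-right
    mean_fragment = len(template) / (count + 1)
    return count, mean_fragment
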