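"""Classification of I-SceI reporter repair junctions.

Sanger reads of cloned repair-junction amplicons are compared against the
reference amplicon by exact-match flank anchoring around the cut site and
sorted into four event categories:

* ``direct``    — re-ligation without any mutation (read == reference),
* ``deletion``  — simple deletion,
* ``delins``    — deletion accompanied by inserted DNA,
* ``insertion`` — insertion at the break site without loss of sequence,

plus ``unclassified`` for reads whose flanks cannot be anchored.  Simple
deletions are additionally scored for junctional microhomology — the length
of identical sequence shared by the two deletion flanks, which makes the
exact deletion placement ambiguous and is a signature of alternative
end joining.  Deletion placement is canonicalized to the leftmost
microhomology-equivalent position; the microhomology length itself is
placement-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

CATEGORIES = ("direct", "deletion", "delins", "insertion", "unclassified")

#: Deletion-size bin edges (half-open [e_i, e_{i+1})): 1, 2-5, 6-20, 21-100, >100 nt.
DEFAULT_SIZE_BINS = (1, 2, 6, 21, 101)
#: Microhomology bin edges: 0, 1-2, 3-5, >=6 nt.
DEFAULT_MH_BINS = (0, 1, 3, 6)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceAmplicon:
    """Reference amplicon with the 0-based position between the two
    nucleotides flanking the expected I-SceI break."""

    sequence: str
    cut_position: int
    name: str = "amplicon"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("reference sequence is empty")
        if set(seq) - set("ACGTN"):
            raise ValueError("reference contains non-ACGTN characters")
        if not 0 < self.cut_position < len(seq):
            raise ValueError("cut_position must lie strictly inside the sequence")


@dataclass(frozen=True)
class JunctionCall:
    read_id: str
    category: str
    del_start: int = 0
    del_end: int = 0
    deletion_size: int = 0
    inserted_seq: str = ""
    microhomology_len: int = 0
    left_anchor_len: int = 0
    right_anchor_len: int = 0


@dataclass
class JunctionSpectrum:
    category_counts: dict[str, int]
    size_hist: np.ndarray
    size_bin_edges: tuple[int, ...]
    mh_hist: np.ndarray
    mh_bin_edges: tuple[int, ...]
    n_total: int


# ---------------------------------------------------------------------------
# anchoring and classification
# ---------------------------------------------------------------------------

def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def anchor_read(read: str, ref: ReferenceAmplicon, min_anchor: int = 10) -> dict | None:
    """Anchor a read to the reference by maximal exact flank matches.

    The left anchor is the longest read prefix matching the reference prefix;
    the right anchor the longest suffix-suffix match.  Both maximal anchors
    must reach ``min_anchor`` or the read is unanchorable (returns None).
    The right anchor is then trimmed so the anchors overlap neither on the
    read nor on the reference, preferring the longer left anchor.  Returns
    ``{"left": L, "right": R}`` with L the anchored prefix length and R the
    anchored suffix length after trimming.
    """
    read = read.upper()
    seq = ref.sequence
    left = _common_prefix_len(read, seq)
    right = _common_prefix_len(read[::-1], seq[::-1])
    if left < min_anchor or right < min_anchor:
        # a read identical to the reference trivially anchors end to end
        if read == seq:
            return {"left": len(read), "right": 0}
        return None
    right = min(right, len(read) - left, len(seq) - left)
    return {"left": left, "right": right}


def classify_junction(
    read: str,
    ref: ReferenceAmplicon,
    min_anchor: int = 10,
    read_id: str = "",
) -> JunctionCall:
    """Classify one read into direct / deletion / delins / insertion.

    The reference gap between the anchors is the deletion; the unmatched read
    middle is the insertion.  Deletions are canonicalized to the leftmost
    microhomology-equivalent placement.  Reads that fail anchoring are
    returned as ``unclassified`` with zeroed fields rather than forced into a
    category.
    """
    read = read.upper()
    anchors = anchor_read(read, ref, min_anchor)
    if anchors is None:
        return JunctionCall(read_id=read_id, category="unclassified")
    left, right = anchors["left"], anchors["right"]
    del_start = left
    del_end = len(ref.sequence) - right
    deletion_size = del_end - del_start
    inserted = read[left : len(read) - right]

    if deletion_size == 0 and not inserted:
        category = "direct"
        del_start = del_end = 0
    elif deletion_size > 0 and not inserted:
        category = "deletion"
        # leftmost placement among microhomology-equivalent deletions
        while del_start > 0 and ref.sequence[del_start - 1] == ref.sequence[del_end - 1]:
            del_start -= 1
            del_end -= 1
    elif deletion_size == 0 and inserted:
        category = "insertion"
        del_start = del_end = 0
    else:
        category = "delins"

    mh = 0
    if category == "deletion":
        mh = microhomology(ref, del_start, del_end)
        left_anchor = del_start
        right_anchor = len(read) - del_start
    else:
        left_anchor = left
        right_anchor = right
    return JunctionCall(
        read_id=read_id,
        category=category,
        del_start=del_start,
        del_end=del_end,
        deletion_size=deletion_size,
        inserted_seq=inserted,
        microhomology_len=mh,
        left_anchor_len=left_anchor,
        right_anchor_len=right_anchor,
    )


def microhomology(ref: ReferenceAmplicon, del_start: int, del_end: int) -> int:
    """Junctional microhomology length of the deletion [del_start, del_end).

    Counts how far the deletion window can slide right plus how far it can
    slide left while producing the identical repaired sequence — i.e. the
    number of alternative placements minus one — capped at the deletion size.
    """
    seq = ref.sequence
    if not (0 <= del_start < del_end <= len(seq)):
        raise ValueError("deletion interval out of bounds")
    size = del_end - del_start
    right = 0
    while del_end + right < len(seq) and seq[del_start + right] == seq[del_end + right]:
        right += 1
    left = 0
    while del_start - 1 - left >= 0 and seq[del_start - 1 - left] == seq[del_end - 1 - left]:
        left += 1
    return min(right + left, size)


# ---------------------------------------------------------------------------
# spectra and I/O
# ---------------------------------------------------------------------------

def spectrum(
    calls: Iterable[JunctionCall],
    size_bins: Sequence[int] = DEFAULT_SIZE_BINS,
    mh_bins: Sequence[int] = DEFAULT_MH_BINS,
    sizes_include_delins: bool = True,
) -> JunctionSpectrum:
    """Category counts plus deletion-size and microhomology histograms.

    Histograms use half-open bins [e_i, e_{i+1}) with a final open-ended bin
    above the last edge.  The size histogram covers simple deletions and
    delins by default (both carry deletions); the microhomology histogram
    covers simple deletions only.  Unclassified reads are counted in
    ``category_counts`` but excluded from histograms.
    """
    size_bins = tuple(size_bins)
    mh_bins = tuple(mh_bins)
    for edges in (size_bins, mh_bins):
        if any(b >= c for b, c in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
    calls = list(calls)
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1

    size_cats = ("deletion", "delins") if sizes_include_delins else ("deletion",)
    sizes = [c.deletion_size for c in calls if c.category in size_cats]
    mhs = [c.microhomology_len for c in calls if c.category == "deletion"]
    size_hist, _ = np.histogram(sizes, bins=list(size_bins) + [np.inf])
    mh_hist, _ = np.histogram(mhs, bins=list(mh_bins) + [np.inf])
    return JunctionSpectrum(
        category_counts=counts,
        size_hist=size_hist,
        size_bin_edges=size_bins,
        mh_hist=mh_hist,
        mh_bin_edges=mh_bins,
        n_total=len(calls),
    )


def classify_fasta(
    reads_path,
    ref: ReferenceAmplicon,
    min_anchor: int = 10,
) -> list[JunctionCall]:
    """Classify every record of a FASTA file of cloned junction reads."""
    return [
        classify_junction(str(rec.seq), ref, min_anchor=min_anchor, read_id=rec.id)
        for rec in SeqIO.parse(str(reads_path), "fasta")
    ]


def read_reference_fasta(path, cut_position: int) -> ReferenceAmplicon:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceAmplicon(sequence=str(rec.seq), cut_position=cut_position, name=rec.id)


def calls_frame(calls: Iterable[JunctionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "category": c.category,
                "del_start": c.del_start,
                "del_end": c.del_end,
                "deletion_size": c.deletion_size,
                "inserted_seq": c.inserted_seq,
                "microhomology_len": c.microhomology_len,
                "left_anchor_len": c.left_anchor_len,
                "right_anchor_len": c.right_anchor_len,
            }
            for c in calls
        ]
    )


def spectrum_frames(spec: JunctionSpectrum) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Category-count, size-histogram, and MH-histogram tables."""
    cat = pd.DataFrame(
        {"category": list(spec.category_counts), "count": list(spec.category_counts.values())}
    )
    cat["proportion"] = cat["count"] / max(spec.n_total, 1)

    def _labels(edges: tuple[int, ...]) -> list[str]:
        labels = []
        for lo, hi in zip(edges, edges[1:]):
            labels.append(str(lo) if hi == lo + 1 else f"{lo}-{hi - 1}")
        labels.append(f">={edges[-1]}")
        return labels

    size = pd.DataFrame({"bin": _labels(spec.size_bin_edges), "count": spec.size_hist})
    mh = pd.DataFrame({"bin": _labels(spec.mh_bin_edges), "count": spec.mh_hist})
    return cat, size, mh
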