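"""Circular-replicon detection from exact terminal overlaps.

A closed circular replicon assembled as a linear contig typically
carries a duplicated stretch: the contig's 5' prefix reappears verbatim
as its 3' suffix. We call a contig circular when the longest exact
(100% identity) prefix/suffix overlap reaches a minimum length, 50 nt by
default, and trim the redundant suffix copy to obtain the circular
sequence. Ambiguous bases (N) never match, and the search is capped at
half the contig length: an apparent self-overlap beyond that indicates a
collapsed repeat rather than a circle.

Only the forward orientation is compared; a reverse-complement
end-to-end join would signal misassembly, not circularity.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_MIN_OVERLAP = 50


@dataclass(frozen=True)
class CircularityCall:
    replicon_id: str
    is_circular: bool
    overlap_len: int
    trimmed_length: int


def _encode_unique_ns(sequence: str) -> list:
    """Map each N to a distinct symbol so N never matches anything."""
    out = []
    counter = 0
    for ch in sequence:
        if ch == "N":
            out.append(-1 - counter)  # unique negative code per N
            counter += 1
        else:
            out.append(ord(ch))
    return out


def terminal_overlap(sequence: str, max_frac: float = 0.5) -> int:
    """Length of the longest exact prefix/suffix overlap.

    Returns the largest k <= max_frac * len(sequence) with
    sequence[:k] == sequence[-k:], treating N as matching nothing;
    0 if no such k exists. Runs in linear time via the KMP border array.
    """
    n = len(sequence)
    if n < 2:
        return 0
    s = _encode_unique_ns(sequence.upper())
    # KMP failure function: border[i] = longest proper border of s[:i+1]
    border = [0] * n
    k = 0
    for i in range(1, n):
        while k > 0 and s[i] != s[k]:
            k = border[k - 1]
        if s[i] == s[k]:
            k += 1
        border[i] = k
    cap = int(max_frac * n)
    k = border[n - 1]
    while k > cap:
        k = border[k - 1] if k > 0 else 0
    return k


def assess(replicon_id: str, sequence: str,
           min_overlap: int = DEFAULT_MIN_OVERLAP,
           max_frac: float = 0.5) -> CircularityCall:
    """Full circularity call for one contig."""
    k = terminal_overlap(sequence, max_frac=max_frac)
    circular = k >= min_overlap
    return CircularityCall(
        replicon_id=replicon_id,
        is_circular=circular,
        overlap_len=k,
        trimmed_length=len(sequence) - k if circular else len(sequence),
    )


def circularize(sequence: str,
                min_overlap: int = DEFAULT_MIN_OVERLAP,
                max_frac: float = 0.5) -> str:
    """Remove the redundant suffix copy of the terminal overlap.

    Raises ValueError when the contig does not meet the circularity
    threshold.
    """
    k = terminal_overlap(sequence, max_frac=max_frac)
    if k < min_overlap:
        raise ValueError(
            f"terminal overlap {k} nt is below the circularity "
            f"threshold of {min_overlap} nt"
        )
    return sequence[:-k]


def rotate_to_start(sequence: str, start: int) -> str:
    """Rotate a circularized sequence so 1-based ``start`` becomes base 1.

    Offered for manually adjusting the origin to the replication system;
    the caller supplies the coordinate.
    """
    if not (1 <= start <= len(sequence)):
        raise ValueError(f"start {start} outside 1..{len(sequence)}")
    i = start - 1
    return sequence[i:] + sequence[:i]
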