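"""American Heart Association 16-segment geometry for the left ventricle.

The LV short-axis stack is split base->apex into basal / mid-cavity / apical
regions covering 35% / 35% / 30% of the myocardium-bearing slices.  Basal and
mid rings carry six 60-degree sectors, the apical ring four 90-degree sectors;
the apical cap (segment 17) is not used.

Angular convention: in-plane angles are ``atan2(row - c_row, col - c_col)``
(image coordinates, rows increasing downward), increasing angle is the
direction in which segment numbering proceeds from the anterior segment
toward the septum.  The angular origin ``alpha0`` is the anterior right
ventricular insertion point, so that:

* basal ring:  1 anterior | 2 anteroseptal | 3 inferoseptal | 4 inferior |
  5 inferolateral | 6 anterolateral   (segment 1 ends at ``alpha0``)
* mid ring:    7..12, same pattern
* apical ring: 13 anterior | 14 septal | 15 inferior | 16 lateral, with
  segment 13 centred on the anterior direction (``alpha0`` - 30 deg).
"""

from __future__ import annotations

import numpy as np

RING_BASAL, RING_MID, RING_APICAL = "basal", "mid", "apical"
RINGS = (RING_BASAL, RING_MID, RING_APICAL)

#: slice-count shares of the three regions, base -> apex
REGION_SHARES = (0.35, 0.35, 0.30)

SEGMENTS_PER_RING = {RING_BASAL: 6, RING_MID: 6, RING_APICAL: 4}
FIRST_SEGMENT = {RING_BASAL: 1, RING_MID: 7, RING_APICAL: 13}
ALL_SEGMENTS = tuple(range(1, 17))


def partition_slices(n_slices: int) -> list[str]:
    """Assign each of ``n_slices`` (ordered base->apex) to a ring.

    Largest-remainder apportionment of the 35/35/30 shares; remainder ties are
    resolved toward the basal region first, then mid.
    """
    if n_slices < 1:
        raise ValueError("need at least one myocardium-bearing slice")
    quotas = [share * n_slices for share in REGION_SHARES]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    # distribute leftover slices by largest remainder, ties toward base
    order = sorted(range(3), key=lambda i: (-remainders[i], i))
    for i in range(n_slices - sum(counts)):
        counts[order[i % 3]] += 1
    out: list[str] = []
    for ring, c in zip(RINGS, counts):
        out.extend([ring] * c)
    return out


def segment_for_angle(alpha: np.ndarray, ring: str, alpha0: float) -> np.ndarray:
    """Vectorized AHA segment id for in-plane angles ``alpha`` (radians).

    ``alpha0`` is the anterior RV insertion angle.  Works for scalars and
    arrays; returns int segment ids of the given ring.
    """
    alpha = np.asarray(alpha, dtype=float)
    if ring in (RING_BASAL, RING_MID):
        idx = np.floor(((alpha - alpha0) % (2 * np.pi)) / (np.pi / 3)).astype(int) % 6
        seg = (idx + 1) % 6 + FIRST_SEGMENT[ring]
    elif ring == RING_APICAL:
        start = alpha0 - np.deg2rad(75.0)  # segment 13 centred 30 deg before alpha0
        idx = np.floor(((alpha - start) % (2 * np.pi)) / (np.pi / 2)).astype(int) % 4
        seg = idx + FIRST_SEGMENT[ring]
    else:
        raise ValueError(f"unknown ring {ring!r}")
    return seg


def segments_in_ring(ring: str) -> tuple[int, ...]:
    first = FIRST_SEGMENT[ring]
    return tuple(range(first, first + SEGMENTS_PER_RING[ring]))


def ring_of_segment(segment: int) -> str:
    if 1 <= segment <= 6:
        return RING_BASAL
    if 7 <= segment <= 12:
        return RING_MID
    if 13 <= segment <= 16:
        return RING_APICAL
    raise ValueError(f"invalid AHA segment id {segment}")


def sector_bounds(segment: int, alpha0: float) -> tuple[float, float]:
    """Angular interval (start, end) of a segment, end = start + width."""
    ring = ring_of_segment(segment)
    if ring == RING_APICAL:
        start0 = alpha0 - np.deg2rad(75.0)
        k = segment - FIRST_SEGMENT[ring]
        width = np.pi / 2
    else:
        # segment ordering 1->2.. maps to sector index (seg-first-1) via inverse
        # of (idx + 1) % 6: sector idx = (seg - first - 1) % 6
        start0 = alpha0
        k = (segment - FIRST_SEGMENT[ring] - 1) % 6
        width = np.pi / 3
    start = start0 + k * width
    return start, start + width
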