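"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive re-derivations of the scoring and hit-typing
rules, written against the rule statements rather than sharing code with
the package.
"""

from __future__ import annotations

import numpy as np


def _runs_of(segs: list[tuple[int, int, int, int]], flag) -> list[tuple[int, int]]:
    """Maximal abutting runs among flagged segments; segs sorted by start."""
    runs = []
    current = None
    for start, end, a, b in segs:
        if flag(a, b):
            if current is not None and start == current[1] + 1:
                current = (current[0], end)
            else:
                if current is not None:
                    runs.append(current)
                current = (start, end)
        else:
            if current is not None:
                runs.append(current)
            current = None
    if current is not None:
        runs.append(current)
    return runs


def oracle_loh(chrom_segs: dict, chrom_lengths: dict, min_length: float = 15e6) -> int:
    """Count B = 0 runs longer than ``min_length`` not spanning a chromosome."""
    total = 0
    for chrom, segs in chrom_segs.items():
        segs = sorted(segs)
        for s, e in _runs_of(segs, lambda a, b: b == 0):
            if (e - s + 1) > min_length and not (s == 1 and e == chrom_lengths[chrom]):
                total += 1
    return total


def oracle_tai(chrom_segs: dict, chrom_lengths: dict, centromeres: dict,
               min_length: float = 0) -> int:
    """Telomere-touching imbalance runs clear of the centromere."""
    total = 0
    for chrom, segs in chrom_segs.items():
        segs = sorted(segs)
        ln = chrom_lengths[chrom]
        cs, ce = centromeres[chrom]
        for s, e in _runs_of(segs, lambda a, b: a != b):
            touches = s == 1 or e == ln
            hits_cen = not (e < cs or s > ce)
            whole = s == 1 and e == ln
            if touches and not hits_cen and not whole and (e - s + 1) >= min_length:
                total += 1
    return total


def oracle_lst(chrom_segs: dict, chrom_lengths: dict, centromeres: dict,
               min_segment: float = 10e6, smoothing: float = 3e6) -> int:
    """Large-scale transitions via an explicit per-arm smoothing loop."""
    total = 0
    for chrom, segs in chrom_segs.items():
        ln = chrom_lengths[chrom]
        cs, ce = centromeres[chrom]
        for arm_lo, arm_hi in ((1, cs - 1), (ce + 1, ln)):
            rows = []
            for s, e, a, b in sorted(segs):
                s2, e2 = max(s, arm_lo), min(e, arm_hi)
                if s2 <= e2:
                    rows.append([s2, e2, a, b])
            # merge equal states across gaps <= smoothing
            def merge(rows):
                out = []
                for r in rows:
                    if out and out[-1][2] == r[2] and out[-1][3] == r[3] \
                            and r[0] - out[-1][1] - 1 <= smoothing:
                        out[-1][1] = r[1]
                    else:
                        out.append(list(r))
                return out

            rows = merge(rows)
            while True:
                small = [r for r in rows if r[1] - r[0] + 1 < smoothing]
                if not small:
                    break
                smallest = min(small, key=lambda r: r[1] - r[0] + 1)
                rows.remove(smallest)
                rows = merge(rows)
            for left, right in zip(rows, rows[1:]):
                if (left[2], left[3]) == (right[2], right[3]):
                    continue
                gap = right[0] - left[1] - 1
                if (
                    gap <= smoothing
                    and left[1] - left[0] + 1 >= min_segment
                    and right[1] - right[0] + 1 >= min_segment
                ):
                    total += 1
    return total


def profile_to_chrom_segs(profile) -> dict:
    """Adapter: SegmentProfile -> {chrom: [(start, end, a, b), ...]}."""
    out = {}
    for row in profile.segments.itertuples(index=False):
        out.setdefault(row.chromosome, []).append(
            (int(row.start), int(row.end), int(row.a), int(row.b))
        )
    return out


def oracle_hit_type(
    a: int,
    b: int,
    has_germline: bool,
    somatic_vafs: list[float],
    purity: float = 1.0,
) -> str:
    """Literal evaluation of the five biallelic criteria at one locus."""
    cn = a + b
    if cn == 0:
        return "BA"
    alpha = a / (2 * cn)
    beta = b / (2 * cn)
    loh = b == 0
    v = sorted((min(1.0, x / purity) for x in somatic_vafs), reverse=True)
    if loh and has_germline:
        return "BA"
    if loh and any(x >= alpha for x in v):
        return "BA"
    if has_germline and any(x >= beta for x in v):
        return "BA"
    if len(v) >= 2 and v[0] >= alpha and v[1] >= beta:
        return "BA"
    return "MA"


def oracle_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by explicit pair counting."""
    wins = ties = 0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1
            elif x == y:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
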