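"""Independent brute-force oracles used to validate the fast paths.

These deliberately share no code with the package implementation: the
seed oracle re-tests every type definition at every offset with plain
string/dict logic, and the energy oracles enumerate every legal structure
explicitly and score it by loop decomposition.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
GU = {("G", "U"), ("U", "G")}


# ---------------------------------------------------------------------------
# seed-match oracle
# ---------------------------------------------------------------------------

def oracle_scan(mirna_seq: str, region_seq: str) -> list[tuple[int, int, str, int | None]]:
    """All typed sites in one region: (start, end, type_name, wobble_pos).

    Tests each of the five definitions independently per 8-nt frame and
    applies the precedence 2t8A1 > 2t8 > 2t7A1 > 2t7 > 1t8GU.  Span rule:
    8 nt for 2t8A1/1t8GU, 7 nt from the frame start for 2t8, 7 nt from
    frame start+1 for 2t7A1, 6 nt from frame start+1 for 2t7.
    """
    m = mirna_seq[:8]
    out = []
    for off in range(len(region_seq) - 7):
        frame = region_seq[off : off + 8]
        wc = {p: (m[p - 1], frame[8 - p]) in WC for p in range(1, 9)}
        gu = {p: (m[p - 1], frame[8 - p]) in GU for p in range(1, 9)}
        a1 = frame[7] == "A"
        is_2t8 = all(wc[p] for p in range(2, 9))
        is_2t7 = all(wc[p] for p in range(2, 8))
        n_gu = sum(gu.values())
        all_paired = all(wc[p] or gu[p] for p in range(1, 9))
        if is_2t8 and a1:
            out.append((off, off + 8, "2t8A1", None))
        elif is_2t8:
            out.append((off, off + 7, "2t8", None))
        elif is_2t7 and a1:
            out.append((off + 1, off + 8, "2t7A1", None))
        elif is_2t7:
            out.append((off + 1, off + 7, "2t7", None))
        elif all_paired and n_gu == 1:
            wob = next(p for p in range(1, 9) if gu[p])
            out.append((off, off + 8, "1t8GU", wob))
    return out


# ---------------------------------------------------------------------------
# duplex (hybridization) oracle
# ---------------------------------------------------------------------------

ALLOWED = WC | GU


def oracle_duplex(x: str, y: str, params) -> float:
    """MFE over every monotone antiparallel pair list between strands
    x and y (both 5'->3'), scored with the same cost model as the DP:
    stack on adjacency, affine bulge/internal otherwise, plus
    duplex_init; the empty duplex scores 0."""
    n, m = len(x), len(y)
    best = 0.0

    def stack_term(i1: int, j1: int, i2: int, j2: int) -> float | None:
        gx, gy = i2 - i1 - 1, j1 - j2 - 1
        if gx + gy > params.max_loop:
            return None
        if gx == 0 and gy == 0:
            from mirspan.energetics import _IDX  # parameter table lookup only

            return params.stack[_IDX[x[i1]]][_IDX[y[j1]]][_IDX[x[i2]]][_IDX[y[j2]]]
        if gx == 0 or gy == 0:
            return params.bulge_init + params.bulge_per_nt * (gx + gy)
        return params.internal_init + params.internal_per_nt * (gx + gy)

    def rec(last_i: int, last_j: int, energy: float) -> None:
        nonlocal best
        for i in range(last_i + 1, n):
            for j in range(last_j - 1, -1, -1):
                if (x[i], y[j]) not in ALLOWED:
                    continue
                if last_i < 0:
                    e = 0.0
                else:
                    term = stack_term(last_i, last_j, i, j)
                    if term is None:
                        continue
                    e = energy + term
                best = min(best, params.duplex_init + e)
                rec(i, j, e)

    rec(-1, m, 0.0)
    return min(0.0, best)


# ---------------------------------------------------------------------------
# folding oracle
# ---------------------------------------------------------------------------

def oracle_fold(seq: str, params, forced_unpaired: tuple[int, ...] = ()) -> float:
    """MFE over every nested secondary structure of ``seq`` (explicit
    enumeration), scored by loop decomposition: hairpin / stack / bulge /
    internal (size-capped) / affine multiloop; exterior bases are free."""
    n = len(seq)
    blocked = set(forced_unpaired)

    def pairable(i: int, j: int) -> bool:
        return (
            (seq[i], seq[j]) in ALLOWED
            and i not in blocked
            and j not in blocked
            and j - i - 1 >= params.min_hairpin
        )

    @lru_cache(maxsize=None)
    def structures(i: int, j: int) -> tuple[frozenset, ...]:
        if i >= j:
            return (frozenset(),)
        out = list(structures(i + 1, j))  # i unpaired
        for k in range(i + params.min_hairpin + 1, j + 1):
            if not pairable(i, k):
                continue
            for inner in structures(i + 1, k - 1):
                for rest in structures(k + 1, j):
                    out.append(inner | rest | {(i, k)})
        return tuple(out)

    def score(pairs: frozenset) -> float | None:
        if not pairs:
            return 0.0
        by_open = dict(sorted(pairs))
        total = 0.0
        for (i, j) in pairs:
            # pairs directly enclosed by (i, j)
            children = []
            k = i + 1
            while k < j:
                if k in by_open:
                    children.append((k, by_open[k]))
                    k = by_open[k] + 1
                else:
                    k += 1
            if not children:
                size = j - i - 1
                total += params.hairpin_init + params.hairpin_per_nt * max(
                    0, size - params.min_hairpin
                )
            elif len(children) == 1:
                (p, q) = children[0]
                g1, g2 = p - i - 1, j - q - 1
                if g1 + g2 > params.max_loop:
                    return None  # outside the model's loop-size bound
                if g1 == 0 and g2 == 0:
                    from mirspan.energetics import _IDX

                    total += params.stack[_IDX[seq[i]]][_IDX[seq[j]]][
                        _IDX[seq[p]]
                    ][_IDX[seq[q]]]
                elif g1 == 0 or g2 == 0:
                    total += params.bulge_init + params.bulge_per_nt * (g1 + g2)
                else:
                    total += params.internal_init + params.internal_per_nt * (
                        g1 + g2
                    )
            else:
                unpaired = (j - i - 1) - sum(q - p + 1 for p, q in children)
                total += (
                    params.multi_init
                    + params.multi_branch * (1 + len(children))
                    + params.multi_unpaired * unpaired
                )
        return total

    best = 0.0
    for pairs in structures(0, n - 1):
        e = score(pairs)
        if e is not None:
            best = min(best, e)
    structures.cache_clear()
    return best
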