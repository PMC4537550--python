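"""Brute-force persistent homology oracle for small clouds.

Textbook implementation kept deliberately naive and independent of the
package: enumerate every simplex of dimension <= 2 under the scale cap, sort
by (filtration value, dimension, vertex tuple), and reduce the full boundary
matrix over GF(p) with plain column-by-column Gaussian elimination.  Used
only by the test suite to certify the fast reduction.
"""

from itertools import combinations


def brute_h1(dm, max_scale, p=2):
    """All H1 (birth, death) pairs; essential classes reported as (birth, None).

    ``dm`` is any square distance matrix indexable as ``dm[i][j]``.
    Zero-persistence pairs (death == birth) are dropped, matching the
    package's convention.
    """
    n = len(dm)
    simplices = []
    for i in range(n):
        simplices.append((0.0, 0, (i,)))
    for i, j in combinations(range(n), 2):
        if dm[i][j] <= max_scale:
            simplices.append((float(dm[i][j]), 1, (i, j)))
    for i, j, k in combinations(range(n), 3):
        f = max(dm[i][j], dm[i][k], dm[j][k])
        if f <= max_scale:
            simplices.append((float(f), 2, (i, j, k)))
    simplices.sort()
    index = {s[2]: idx for idx, s in enumerate(simplices)}

    def boundary(verts):
        # d[v0..vk] = sum_i (-1)^i [.. omit v_i ..]
        col = {}
        for i in range(len(verts)):
            face = verts[:i] + verts[i + 1 :]
            col[index[face]] = (-1) ** i % p
        return {r: c for r, c in col.items() if c}

    lows = {}  # low row position -> reduced column (dict row -> coeff)
    low_owner = {}  # low row position -> column position that owns it
    positive = set()
    for pos, (_, dim, verts) in enumerate(simplices):
        if dim == 0:
            positive.add(pos)
            continue
        col = boundary(verts)
        while col:
            low = max(col)
            if low not in lows:
                lows[low] = col
                low_owner[low] = pos
                break
            other = lows[low]
            factor = (col[low] * pow(other[low], -1, p)) % p
            for r, c in other.items():
                col[r] = (col.get(r, 0) - factor * c) % p
            col = {r: c for r, c in col.items() if c}
        if not col:
            positive.add(pos)

    intervals = []
    for pos, (f, dim, _) in enumerate(simplices):
        if dim != 1 or pos not in positive:
            continue
        if pos in low_owner:
            death = simplices[low_owner[pos]][0]
            if death > f:
                intervals.append((f, death))
        else:
            intervals.append((f, None))
    return sorted(intervals, key=lambda t: (t[0], t[1] is None, t[1] or 0.0))
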