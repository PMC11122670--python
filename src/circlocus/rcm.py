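"""Reverse complementary matches (RCMs) between circRNA-flanking introns.

Inverted intronic repeats base-pair across the circularized exon block and
promote backsplicing. This module finds them with a seed-and-extend local
aligner run between the upstream intron and the reverse complement of the
downstream intron: exact ``word_size`` seeds, X-drop ungapped extension,
then optional affine-gap X-drop extension from both ends, followed by
redundancy resolution. Default scoring mimics blastn (+2/-3, gap -5/-2,
word 11); diverged repeats (identity near 0.85) leave exact-match runs of
only ~5-6 nt between mismatches, so sensitive scans should drop word_size
to 5-7 at some cost in speed.

Hit coordinates are half-open: ``up_*`` in the upstream intron,
``down_*`` in the original (unreversed) downstream intron frame.
``ops`` records the alignment column-by-column ('=' match, 'X' mismatch,
'D' gap in the downstream strand, 'I' gap in the upstream strand) so the
score is exactly recomputable from the reported intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

from .seqs import revcomp


@dataclass(frozen=True)
class RcmParams:
    word_size: int = 11
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    xdrop: int = 20
    min_score: int = 30
    min_length: int = 20
    max_hits: int = 100
    overlap_frac: float = 0.5   # hits sharing more than this of either interval conflict
    gapped: bool = True
    gap_trigger: int = 18       # ungapped score needed to attempt gapped extension

    def __post_init__(self):
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be non-positive scores")
        if self.match <= 0:
            raise ValueError("match score must be positive")

    @classmethod
    def sensitive(cls, **overrides) -> "RcmParams":
        """Profile for recovering short, diverged repeats (identity ~0.85).

        Word size 5 guarantees a seed even when mismatches every 6-7 nt leave
        only 5-6 nt exact runs; +1/-3 scoring keeps alignment endpoints inside
        >=75%-identity sequence, so reported identities track the repeat
        rather than lucky flanking matches; min_score is rescaled to the
        +1 match score.
        """
        kw = dict(word_size=5, match=1, mismatch=-3, min_score=20, min_length=20)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class RCMHit:
    up_start: int
    up_end: int
    down_start: int
    down_end: int
    length: int          # alignment columns
    identity: float
    score: int
    n_gaps: int          # gap columns across both strands
    ops: str = ""
    repeat_overlap: tuple[str, ...] = field(default_factory=tuple)

    @property
    def up_interval(self) -> tuple[int, int]:
        return self.up_start, self.up_end

    @property
    def down_interval(self) -> tuple[int, int]:
        return self.down_start, self.down_end


def score_ops(ops: str, params: RcmParams) -> int:
    """Recompute an alignment score from its column ops (affine gaps)."""
    score = 0
    prev = ""
    for op in ops:
        if op == "=":
            score += params.match
        elif op == "X":
            score += params.mismatch
        elif op in "ID":
            score += params.gap_extend
            if prev != op:
                score += params.gap_open
        else:
            raise ValueError(f"unknown op {op!r}")
        prev = op
    return score


def _sub(a: str, b: str, p: RcmParams) -> int:
    return p.match if a == b and a != "N" else p.mismatch


def _ungapped_extend(a: str, b: str, i: int, j: int, k: int, p: RcmParams):
    """X-drop ungapped extension of an exact seed a[i:i+k]==b[j:j+k].

    Returns (i0, j0, i1, j1, score). Ties in the running maximum prefer the
    longer extension so mirrored searches stay symmetric.
    """
    score = k * p.match
    best = score
    i1, j1 = i + k, j + k
    x, y = i + k, j + k
    run = score
    while x < len(a) and y < len(b):
        run += _sub(a[x], b[y], p)
        x += 1
        y += 1
        if run >= best:
            best, i1, j1 = run, x, y
        elif best - run > p.xdrop:
            break
    score = best
    best = score
    i0, j0 = i, j
    x, y = i - 1, j - 1
    run = score
    while x >= 0 and y >= 0:
        run += _sub(a[x], b[y], p)
        if run >= best:
            best, i0, j0 = run, x, y
        elif best - run > p.xdrop:
            break
        x -= 1
        y -= 1
    return i0, j0, i1, j1, best


_NEG = -(10 ** 9)
_MAX_CELLS = 500_000


def _gapped_extend(a: str, b: str, p: RcmParams):
    """Affine-gap X-drop extension aligning prefixes of ``a`` and ``b``.

    Anchored at (0, 0); explores antidiagonals, pruning cells whose best
    state falls more than ``xdrop`` below the running optimum. Returns
    (alen, blen, score, ops) for the best-scoring extension; ops are
    forward-order columns. Cell budget bounds pathological inputs.
    """
    go, ge = p.gap_open, p.gap_extend
    # cells[(x, y)] = (M, Gx, Gy): x bases of a consumed, y of b;
    # M ends in an aligned column, Gx in a gap consuming a, Gy consuming b.
    cells: dict[tuple[int, int], tuple[int, int, int]] = {(0, 0): (0, _NEG, _NEG)}
    best_score, best_cell = 0, (0, 0)
    prev2: list[tuple[int, int]] = []   # antidiagonal d-2 (feeds diagonal moves)
    prev1: list[tuple[int, int]] = [(0, 0)]  # antidiagonal d-1 (feeds gap moves)
    n_cells = 1
    d = 0
    while (prev1 or prev2) and n_cells < _MAX_CELLS:
        d += 1
        nxt: dict[tuple[int, int], tuple[int, int, int]] = {}
        candidates = {(x + 1, y) for x, y in prev1} | {(x, y + 1) for x, y in prev1} \
            | {(x + 1, y + 1) for x, y in prev2}
        for (x, y) in sorted(candidates):
            if x > len(a) or y > len(b):
                continue
            m = gx = gy = _NEG
            diag = cells.get((x - 1, y - 1))
            if diag is not None and x >= 1 and y >= 1:
                m = max(diag) + _sub(a[x - 1], b[y - 1], p)
            up = cells.get((x - 1, y))
            if up is not None:
                gx = max(up[0] + go + ge, up[1] + ge)
            left = cells.get((x, y - 1))
            if left is not None:
                gy = max(left[0] + go + ge, left[2] + ge)
            hi = max(m, gx, gy)
            if hi <= _NEG or best_score - hi > p.xdrop:
                continue
            nxt[(x, y)] = (m, gx, gy)
            if m > best_score or (m == best_score and (x, y) > best_cell):
                best_score, best_cell = m, (x, y)
        cells.update(nxt)
        prev2, prev1 = prev1, list(nxt)
        n_cells += len(nxt)
    # traceback from best_cell (state M unless origin)
    ops: list[str] = []
    x, y = best_cell
    state = 0 if (x, y) != (0, 0) else -1
    while (x, y) != (0, 0):
        m, gx, gy = cells[(x, y)]
        if state == 0:
            ops.append("=" if a[x - 1] == b[y - 1] and a[x - 1] != "N" else "X")
            prev = cells[(x - 1, y - 1)]
            target = m - _sub(a[x - 1], b[y - 1], p)
            state = max(range(3), key=lambda s: (prev[s] == target, -s))
            x, y = x - 1, y - 1
        elif state == 1:  # gap consuming a: column 'D' (gap in b strand)
            ops.append("D")
            prev = cells[(x - 1, y)]
            state = 0 if prev[0] + go + ge == gx else 1
            x -= 1
        else:  # gap consuming b
            ops.append("I")
            prev = cells[(x, y - 1)]
            state = 0 if prev[0] + go + ge == gy else 2
            y -= 1
    ops.reverse()
    return best_cell[0], best_cell[1], best_score, "".join(ops)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _conflicts(h1: RCMHit, h2: RCMHit, frac: float) -> bool:
    for iv1, iv2 in ((h1.up_interval, h2.up_interval),
                     (h1.down_interval, h2.down_interval)):
        ov = _overlap(iv1, iv2)
        if ov > frac * (iv1[1] - iv1[0]) or ov > frac * (iv2[1] - iv2[0]):
            return True
    return False


def find_rcm(up_intron: str, down_intron: str,
             params: RcmParams | None = None) -> list[RCMHit]:
    """All reverse-complementary matches between two flanking introns.

    Aligns ``up_intron`` against revcomp(``down_intron``); downstream
    coordinates are reported back in the original downstream frame. Output
    is deterministic: score-descending, then upstream start.
    """
    p = params or RcmParams()
    a = up_intron.upper()
    if not a or not down_intron:
        raise ValueError("empty intron sequence")
    b = revcomp(down_intron.upper())
    k = p.word_size
    if min(len(a), len(b)) < k:
        return []

    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        w = a[i:i + k]
        if "N" not in w:
            index.setdefault(w, []).append(i)

    raw: list[RCMHit] = []
    seen_intervals: set[tuple[int, int, int, int]] = set()
    # every seed is extended independently (the best segment CONTAINING the
    # seed), so a weak flanking match can never shadow a stronger segment on
    # the same diagonal; the only safe shortcut is skipping seeds inside a
    # previously found perfect-identity segment, whose re-extension provably
    # reproduces the same interval
    perfect: dict[int, tuple[int, int]] = {}
    for j in range(len(b) - k + 1):
        w = b[j:j + k]
        if "N" in w:
            continue
        for i in index.get(w, ()):
            diag = i - j
            cov = perfect.get(diag)
            if cov and cov[0] <= j and j + k <= cov[1]:
                continue
            i0, j0, i1, j1, su = _ungapped_extend(a, b, i, j, k, p)
            if su == (i1 - i0) * p.match:
                perfect[diag] = (j0, j1)
            ops = "".join("=" if a[x] == b[y] and a[x] != "N" else "X"
                          for x, y in zip(range(i0, i1), range(j0, j1)))
            score = su
            gapped = p.gapped and p.gap_open + p.gap_extend > -p.xdrop
            if gapped and su >= p.gap_trigger:
                la, lb, ls, lops = _gapped_extend(a[:i0][::-1], b[:j0][::-1], p)
                ra, rb, rs, rops = _gapped_extend(a[i1:], b[j1:], p)
                i0, j0 = i0 - la, j0 - lb
                i1, j1 = i1 + ra, j1 + rb
                ops = lops[::-1] + ops + rops
                score = su + ls + rs
            if score < p.min_score or len(ops) < p.min_length:
                continue
            key = (i0, i1, j0, j1)
            if key in seen_intervals:
                continue
            seen_intervals.add(key)
            n_eq = ops.count("=")
            n_gap = ops.count("I") + ops.count("D")
            raw.append(RCMHit(
                up_start=i0, up_end=i1,
                down_start=len(down_intron) - j1, down_end=len(down_intron) - j0,
                length=len(ops), identity=n_eq / len(ops),
                score=score, n_gaps=n_gap, ops=ops))

    raw.sort(key=lambda h: (-h.score, h.up_start, h.down_start))
    kept: list[RCMHit] = []
    for h in raw:
        if all(not _conflicts(h, other, p.overlap_frac) for other in kept):
            kept.append(h)
    return kept[: p.max_hits]


def annotate_repeats(hits: list[RCMHit],
                     up_repeats: list[tuple[int, int, str]] | None = None,
                     down_repeats: list[tuple[int, int, str]] | None = None) -> list[RCMHit]:
    """Attach names of repeat intervals (intron-local coordinates) that
    overlap either side of each hit by >= 1 nt; hit order is preserved."""
    up_tree, down_tree = IntervalTree(), IntervalTree()
    for s, e, name in up_repeats or []:
        up_tree.addi(s, e, name)
    for s, e, name in down_repeats or []:
        down_tree.addi(s, e, name)
    out = []
    for h in hits:
        names = sorted({iv.data for iv in up_tree.overlap(h.up_start, h.up_end)} |
                       {iv.data for iv in down_tree.overlap(h.down_start, h.down_end)})
        out.append(replace(h, repeat_overlap=tuple(names)))
    return out


def alignment_text(hit: RCMHit, up_intron: str, down_intron: str) -> str:
    """Human-readable full alignment of one RCM (upstream vs revcomp of
    downstream), for the text dump accompanying the RCM table."""
    b = revcomp(down_intron)
    j0 = len(down_intron) - hit.down_end
    ai, bi = hit.up_start, j0
    top, mid, bot = [], [], []
    for op in hit.ops:
        if op in "=X":
            top.append(up_intron[ai]); bot.append(b[bi])
            mid.append("|" if op == "=" else " ")
            ai += 1; bi += 1
        elif op == "D":
            top.append(up_intron[ai]); bot.append("-"); mid.append(" ")
            ai += 1
        else:
            top.append("-"); bot.append(b[bi]); mid.append(" ")
            bi += 1
    header = (f"up {hit.up_start}-{hit.up_end}  down {hit.down_start}-{hit.down_end} "
              f"(revcomp)  length={hit.length} identity={hit.identity:.3f} "
              f"score={hit.score} gaps={hit.n_gaps}")
    lines = [header]
    for k in range(0, len(top), 60):
        lines += ["".join(top[k:k + 60]), "".join(mid[k:k + 60]),
                  "".join(bot[k:k + 60]), ""]
    return "\n".join(lines)


def rank_candidates(hits: list[RCMHit], top_k: int) -> list[RCMHit]:
    """Promising circularization candidates: longest, then most identical,
    then highest-scoring, ties broken by upstream position."""
    if top_k <= 0:
        return []
    ranked = sorted(hits, key=lambda h: (-h.length, -h.identity, -h.score, h.up_start))
    return ranked[:top_k]
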