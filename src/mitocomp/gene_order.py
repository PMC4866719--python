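"""Circular gene-order normalization, comparison and rearrangement events.

Gene orders are signed circular sequences of gene labels. Event inference is
deliberately heuristic and greedy, with a fixed priority (duplication/loss,
then inversion, then translocation/adjacent swap): arrangements in comparative
mitogenomics are annotated by parsimony of description, not by optimizing a
rearrangement distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from mitocomp.model import PCG_LABELS, base_label


@dataclass
class GeneOrder:
    labels: list[str]
    strands: list[str] | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("gene order must contain at least one gene")
        if self.strands is None:
            self.strands = ["+"] * len(self.labels)
        if len(self.strands) != len(self.labels):
            raise ValueError("labels and strands must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneOrder)
            and self.labels == other.labels
            and self.strands == other.strands
            and self.circular == other.circular
        )

    def signed(self) -> list[tuple[str, str]]:
        return list(zip(self.labels, self.strands))


@dataclass
class RearrangementEvent:
    """One gene-order change: translocation, adjacent_swap, inversion,
    duplication or loss."""

    kind: str
    genes: list[str]
    from_index: int | None = None
    to_index: int | None = None
    span: tuple[str, str] | None = None
    positions: list[int] = field(default_factory=list)

    KINDS = ("translocation", "adjacent_swap", "inversion", "duplication", "loss")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.genes:
            raise ValueError("event must involve at least one gene")


def normalize(o: GeneOrder, anchor: str = "cox1") -> GeneOrder:
    """Rotate a circular order so ``anchor`` comes first on the + strand.

    If the anchor lies on the minus strand the whole order is reversed and all
    strands flipped (reading the circle from the other side), so comparisons
    are orientation-free. Idempotent.
    """
    hits = [i for i, lab in enumerate(o.labels) if lab == anchor]
    if len(hits) != 1:
        raise ValueError(
            f"anchor {anchor!r} occurs {len(hits)} times; need exactly one"
        )
    i = hits[0]
    labels, strands = list(o.labels), list(o.strands)
    if strands[i] == "-":
        labels = labels[::-1]
        strands = ["-" if s == "+" else "+" for s in strands[::-1]]
        i = len(labels) - 1 - i
    if o.circular:
        labels = labels[i:] + labels[:i]
        strands = strands[i:] + strands[:i]
    return GeneOrder(labels=labels, strands=strands, circular=o.circular)


def _pcg_only(o: GeneOrder) -> GeneOrder:
    keep = [(lab, s) for lab, s in o.signed() if base_label(lab) in PCG_LABELS]
    if not keep:
        raise ValueError("order contains no protein-coding genes")
    return GeneOrder([l for l, _ in keep], [s for _, s in keep], o.circular)


def pcg_order_identical(a: GeneOrder, b: GeneOrder) -> bool:
    """True iff the protein-coding-gene subsequences match (cyclically for
    circular orders), labels and strands."""
    pa, pb = _pcg_only(a), _pcg_only(b)
    if Counter(pa.labels) != Counter(pb.labels):
        return False
    if "cox1" in pa.labels and pa.labels.count("cox1") == 1 == pb.labels.count("cox1"):
        return normalize(pa).signed() == normalize(pb).signed()
    # fallback: try every rotation (and reflection for circular orders)
    sa, sb = pa.signed(), pb.signed()
    if not a.circular:
        return sa == sb
    n = len(sb)
    flipped = [(l, "-" if s == "+" else "+") for l, s in sb[::-1]]
    for cand in (sb, flipped):
        for k in range(n):
            if sa == cand[k:] + cand[:k]:
                return True
    return False


def _adjacency_set(o: GeneOrder) -> set[frozenset]:
    """Signed cyclic adjacencies, direction-free: the adjacency x(+)->y(+) is
    the same when read from the other strand as y(-)->x(-)."""
    pairs = o.signed()
    n = len(pairs)
    idx = range(n) if o.circular else range(n - 1)
    out = set()
    for i in idx:
        (x, sx), (y, sy) = pairs[i], pairs[(i + 1) % n]
        fwd = (x, sx, y, sy)
        rev = (y, "-" if sy == "+" else "+", x, "-" if sx == "+" else "+")
        out.add(frozenset({fwd, rev}))
    return out


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of signed cyclic adjacencies of ``a`` absent from ``b``.

    Requires the same duplicate-free label multiset; duplicated labels make
    adjacency pairing ambiguous, so callers should resolve duplications first
    (see :func:`detect_duplications`).
    """
    ca, cb = Counter(a.labels), Counter(b.labels)
    dupes = [l for l, c in (ca | cb).items() if c > 1]
    if dupes:
        raise ValueError(
            f"duplicated labels {sorted(dupes)}: run detect_duplications and "
            "resolve copies before computing breakpoint distance"
        )
    if ca != cb:
        raise ValueError("orders must share the same label multiset")
    return len(_adjacency_set(a) - _adjacency_set(b))


def detect_duplications(o: GeneOrder) -> list[tuple[str, int, list[int]]]:
    """Labels present more than once, with copy count and positions."""
    counts = Counter(base_label(l) for l in o.labels)
    out = []
    for lab, c in counts.items():
        if c >= 2:
            pos = [i for i, l in enumerate(o.labels) if base_label(l) == lab]
            out.append((lab, c, pos))
    out.sort(key=lambda t: t[2][0])
    return out


def _lcs_keep(ref: list, query: list) -> list[bool]:
    """Longest common subsequence; returns a keep-mask over ``query``."""
    n, m = len(ref), len(query)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = dp[i], dp[i + 1]
        for j in range(m - 1, -1, -1):
            if ref[i] == query[j]:
                row[j] = nxt[j + 1] + 1
            else:
                row[j] = max(nxt[j], row[j + 1])
    keep = [False] * m
    i = j = 0
    while i < n and j < m:
        if ref[i] == query[j]:
            keep[j] = True
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return keep


def detect_events(query: GeneOrder, ref: GeneOrder) -> list[RearrangementEvent]:
    """Greedy inference of the rearrangement events separating two orders.

    Pipeline: (1) label multiset difference gives duplications and losses;
    (2) elements off a signed longest-common-subsequence scaffold are grouped
    into maximal runs and classified as inversions (reversed, strand-flipped
    runs), adjacent swaps (two neighbours exchanged) or translocations.
    Designed to name single events exactly; composite events are best-effort.
    """
    q = normalize(query) if "cox1" in query.labels else query
    r = normalize(ref) if "cox1" in ref.labels else ref

    events: list[RearrangementEvent] = []

    qc = Counter(base_label(l) for l in q.labels)
    rc = Counter(base_label(l) for l in r.labels)

    q_sig = [(base_label(l), s) for l, s in q.signed()]
    r_sig = [(base_label(l), s) for l, s in r.signed()]

    # 1) duplications / losses ------------------------------------------------
    drop_q: set[int] = set()
    drop_r: set[int] = set()
    for lab in sorted(set(qc) | set(rc), key=lambda l: [i for i, (b, _) in enumerate(r_sig) if b == l] or [len(r_sig)]):
        extra = qc[lab] - rc[lab]
        if extra > 0:
            pos = [i for i, (b, _) in enumerate(q_sig) if b == lab]
            events.append(
                RearrangementEvent("duplication", [lab] * min(extra + rc[lab], qc[lab]),
                                   positions=pos)
            )
            # keep the copy that best preserves reference context: the first
            for p in pos[1:][:extra] if rc[lab] else pos:
                drop_q.add(p)
        elif extra < 0:
            pos = [i for i, (b, _) in enumerate(r_sig) if b == lab]
            events.append(RearrangementEvent("loss", [lab] * (-extra), positions=pos))
            for p in pos[: -extra] if qc[lab] else pos:
                drop_r.add(p)

    q_idx = [i for i in range(len(q_sig)) if i not in drop_q]
    r_idx = [i for i in range(len(r_sig)) if i not in drop_r]
    Q = [q_sig[i] for i in q_idx]
    Rf = [r_sig[i] for i in r_idx]

    if Counter(Q) == Counter(Rf) and Q == Rf:
        return _sorted_events(events, r_sig)

    # 2) + 3) scaffold analysis ----------------------------------------------
    keep = _lcs_keep(Rf, Q)
    moved = [j for j, k in enumerate(keep) if not k]
    r_pos = {}
    for i, (lab, _) in enumerate(Rf):
        r_pos.setdefault(lab, []).append(i)

    # group moved elements into maximal runs of consecutive query positions
    runs: list[list[int]] = []
    for j in moved:
        if runs and j == runs[-1][-1] + 1:
            runs[-1].append(j)
        else:
            runs.append([j])

    for run in runs:
        labs = [Q[j][0] for j in run]
        strands = [Q[j][1] for j in run]
        ref_positions = [r_pos[l][0] for l in labs if l in r_pos]
        # inversion: run is a contiguous reference block, reversed, strands flipped
        if len(ref_positions) == len(run):
            rev = ref_positions[::-1]
            contiguous = rev == list(range(rev[0], rev[0] + len(rev)))
            flipped = all(
                s != Rf[p][1] for s, p in zip(strands, ref_positions)
            )
            if contiguous and flipped:
                events.append(
                    RearrangementEvent(
                        "inversion", labs, span=(labs[-1], labs[0]), positions=run
                    )
                )
                continue
        # adjacent swap: ref ...w x y... ; query ...w y x...
        if len(run) == 1:
            j = run[0]
            lab = labs[0]
            ri = r_pos.get(lab, [None])[0]
            if ri is not None:
                succ = Rf[ri + 1][0] if ri + 1 < len(Rf) else None
                pred = Rf[ri - 1][0] if ri >= 1 else None
                q_prev = Q[j - 1][0] if j >= 1 else None
                q_next = Q[j + 1][0] if j + 1 < len(Q) else None
                if q_prev == succ:
                    # x now follows its reference successor y
                    events.append(
                        RearrangementEvent(
                            "adjacent_swap", [lab, succ],
                            from_index=ri, to_index=j, positions=[j - 1, j],
                        )
                    )
                    continue
                if q_next == pred:
                    events.append(
                        RearrangementEvent(
                            "adjacent_swap", [pred, lab],
                            from_index=ri - 1, to_index=j, positions=[j, j + 1],
                        )
                    )
                    continue
        events.append(
            RearrangementEvent(
                "translocation", labs,
                from_index=ref_positions[0] if ref_positions else None,
                to_index=run[0], positions=run,
            )
        )

    return _sorted_events(events, r_sig)


def _sorted_events(events: list[RearrangementEvent], r_sig) -> list[RearrangementEvent]:
    first_ref = {lab: i for i, (lab, _) in reversed(list(enumerate(r_sig)))}

    def key(e: RearrangementEvent) -> int:
        if e.from_index is not None:
            return e.from_index
        return min((first_ref.get(g, len(r_sig)) for g in e.genes), default=len(r_sig))

    return sorted(events, key=key)


def syntenic_blocks(a: GeneOrder, b: GeneOrder) -> list[list[str]]:
    """Maximal runs of genes contiguous and co-oriented in both orders.

    Works on the labels shared by both orders (others are ignored); returns a
    cover of the shared labels as label runs in ``a``'s order. Cyclic-aware:
    a block may wrap around the origin of ``a``. A block that appears reversed
    and strand-flipped in ``b`` (same segment read from the other side) still
    counts as syntenic.
    """
    a_sig = [(base_label(l), s) for l, s in a.signed()]
    b_sig = [(base_label(l), s) for l, s in b.signed()]
    shared = {l for l, _ in a_sig} & {l for l, _ in b_sig}
    if not shared:
        return []
    fa = [(l, s) for l, s in a_sig if l in shared]
    fb = [(l, s) for l, s in b_sig if l in shared]
    if Counter(l for l, _ in fa) != Counter(l for l, _ in fb):
        # duplicated shared labels: fall back to singleton blocks
        return [[l] for l, _ in fa]
    adj_b = _adjacency_set(GeneOrder([l for l, _ in fb], [s for _, s in fb], b.circular))
    n = len(fa)
    idx = range(n) if a.circular and n > 1 else range(n - 1)
    good = set()
    for i in idx:
        (x, sx), (y, sy) = fa[i], fa[(i + 1) % n]
        fwd = (x, sx, y, sy)
        rev = (y, "-" if sy == "+" else "+", x, "-" if sx == "+" else "+")
        if frozenset({fwd, rev}) in adj_b:
            good.add(i)
    if len(good) == n and a.circular:
        return [[l for l, _ in fa]]
    # split at bad adjacencies
    blocks: list[list[str]] = []
    start = 0
    if a.circular and n > 1:
        # begin right after a bad adjacency so wrap-around blocks stay intact
        bad = [i for i in range(n) if i not in good]
        start = (bad[0] + 1) % n if bad else 0
    cur = [fa[start][0]]
    for k in range(1, n):
        i = (start + k - 1) % n
        j = (start + k) % n
        if i in good:
            cur.append(fa[j][0])
        else:
            blocks.append(cur)
            cur = [fa[j][0]]
    blocks.append(cur)
    return blocks
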