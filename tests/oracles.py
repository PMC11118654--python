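"""Independent brute-force oracles used by the tests.

Everything here recomputes expected results from first principles —
exhaustive enumeration of category definitions, per-base tallies, direct
string scanning — deliberately avoiding the package's own classification
code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import nnls

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# --- SBS-96: enumerate all labels, classify by membership testing ----------


def all_sbs96_labels() -> list[str]:
    labels = []
    for ref in "CT":
        for alt in "ACGT":
            if alt == ref:
                continue
            for five in "ACGT":
                for three in "ACGT":
                    labels.append(f"{five}[{ref}>{alt}]{three}")
    return labels


def sbs96_oracle(tri: str, ref: str, alt: str) -> str:
    """Find the unique label among the 96 matching the event.

    A label matches when its (flank, ref, alt) equal the event read
    directly or read on the complementary strand via explicit complement
    tables.
    """
    assert tri[1] == ref
    matches = []
    for label in all_sbs96_labels():
        five, rest = label.split("[", 1)
        sub, three = rest.split("]")
        lref, lalt = sub.split(">")
        direct = (five, lref, lalt, three) == (tri[0], ref, alt, tri[2])
        flipped = (
            _COMP[three],
            _COMP[lref],
            _COMP[lalt],
            _COMP[five],
        ) == (tri[0], ref, alt, tri[2])
        if direct or flipped:
            matches.append(label)
    assert len(matches) == 1, f"{tri} {ref}>{alt}: {matches}"
    return matches[0]


# --- DBS-78: equivalence classes of doublet substitutions ------------------


def all_dbs_events() -> list[tuple[str, str]]:
    events = []
    for ref in map("".join, itertools.product("ACGT", repeat=2)):
        for alt in map("".join, itertools.product("ACGT", repeat=2)):
            if alt[0] != ref[0] and alt[1] != ref[1]:
                events.append((ref, alt))
    return events


def dbs_equivalent(a: tuple[str, str], b: tuple[str, str]) -> bool:
    return a == b or (_rc(a[0]), _rc(a[1])) == b


def dbs_class_count() -> int:
    events = all_dbs_events()
    seen = set()
    for ref, alt in events:
        seen.add(frozenset({(ref, alt), (_rc(ref), _rc(alt))}))
    return len(seen)


# --- ID-83: direct string scanning -----------------------------------------


def id83_oracle(seq: str, pos: int, ref: str, alt: str) -> str:
    """Classify a left-aligned anchored indel by scanning the raw sequence.

    Unlike the implementation, runs and repeat copies are counted in both
    directions (on valid left-aligned input the upstream side contributes
    nothing, so the answers agree).
    """
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    assert k >= 1
    if len(ref) > len(alt):  # deletion
        deleted = ref[k:]
        s0 = pos - 1 + k  # 0-based first deleted position
        L = len(deleted)
        if L == 1:
            b = deleted
            run = 0
            i = s0
            while i < len(seq) and seq[i] == b:
                run += 1
                i += 1
            i = s0 - 1
            while i >= 0 and seq[i] == b:
                run += 1
                i -= 1
            pyr = b if b in "CT" else _COMP[b]
            return f"1:Del:{pyr}:{min(run - 1, 5)}"
        copies = 0
        i = s0 + L
        while seq[i : i + L] == deleted:
            copies += 1
            i += L
        i = s0 - L
        while i >= 0 and seq[i : i + L] == deleted:
            copies += 1
            i -= L
        size = min(L, 5)
        if copies > 0:
            return f"{size}:Del:R:{min(copies, 5)}"
        down = seq[s0 + L :]
        up = seq[:s0]
        mh = 0
        for j in range(1, L):
            if deleted[:j] == down[:j]:
                mh = max(mh, j)
            if deleted[L - j :] == up[len(up) - j :]:
                mh = max(mh, j)
        if mh > 0:
            return f"{size}:Del:M:{min(mh, 5)}"
        return f"{size}:Del:R:0"
    # insertion after 0-based anchor index a0
    inserted = alt[k:]
    a0 = pos - 1 + k - 1
    L = len(inserted)
    if L == 1:
        b = inserted
        run = 0
        i = a0 + 1
        while i < len(seq) and seq[i] == b:
            run += 1
            i += 1
        i = a0
        while i >= 0 and seq[i] == b:
            run += 1
            i -= 1
        pyr = b if b in "CT" else _COMP[b]
        return f"1:Ins:{pyr}:{min(run, 5)}"
    copies = 0
    i = a0 + 1
    while seq[i : i + L] == inserted:
        copies += 1
        i += L
    i = a0 + 1 - L
    while i >= 0 and seq[i : i + L] == inserted:
        copies += 1
        i -= L
    return f"{min(L, 5)}:Ins:R:{min(copies, 5)}"


# --- left alignment of randomly generated indels ---------------------------


def left_align_deletion(seq: str, s0: int, L: int) -> int:
    """Shift a deletion of seq[s0:s0+L] (0-based) left as far as possible."""
    while s0 > 0 and seq[s0 - 1] == seq[s0 + L - 1]:
        s0 -= 1
    return s0


def left_align_insertion(seq: str, a0: int, ins: str) -> tuple[int, str]:
    """Shift an insertion (after 0-based index a0) left; returns (a0, allele)."""
    while a0 >= 0 and seq[a0] == ins[-1]:
        ins = ins[-1] + ins[:-1]
        a0 -= 1
    return a0, ins


# --- genome aberration: per-base tally -------------------------------------


def aberration_oracle(segments, lengths: dict[str, int]) -> float:
    state = {c: np.zeros(n, dtype=np.int8) for c, n in lengths.items()}
    aberr = {c: np.zeros(n, dtype=np.int8) for c, n in lengths.items()}
    for seg in segments:
        sl = slice(seg.start - 1, seg.end)
        assert not state[seg.chromosome][sl].any(), "overlap in oracle input"
        state[seg.chromosome][sl] = 1
        if (seg.total_cn, seg.minor_cn) != (2, 1):
            aberr[seg.chromosome][sl] = 1
    covered = sum(int(v.sum()) for v in state.values())
    bad = sum(int(v.sum()) for v in aberr.values())
    return bad / covered if covered else 0.0


# --- exhaustive sparse-assignment oracle ------------------------------------


def stagewise_fixed_point_check(P, y, activities, add_penalty, remove_penalty):
    """Verify a reported solution against exhaustive support enumeration.

    Checks (1) activities equal the NNLS fit restricted to the reported
    support, (2) no excluded candidate raises the reconstruction cosine by
    more than the addition penalty, and (3) every supported signature
    costs more than the removal penalty to drop — the defining conditions
    of the stagewise fit, evaluated over all single-move neighbors.
    """

    def cos(v):
        ny, nv = np.linalg.norm(y), np.linalg.norm(v)
        return 0.0 if ny == 0 or nv == 0 else float(y @ v / (ny * nv))

    support = [i for i, a in enumerate(activities) if a > 0]
    x, _ = nnls(P[:, support], y) if support else (np.zeros(0), 0.0)
    fit = np.zeros(len(activities))
    for pos, i in enumerate(support):
        fit[i] = x[pos]
    assert np.allclose(fit, activities, rtol=1e-8, atol=1e-8), "not the NNLS fit on its support"
    current = cos(P[:, support] @ x) if support else 0.0
    for i in range(len(activities)):
        if i in support:
            continue
        trial = support + [i]
        xt, _ = nnls(P[:, trial], y)
        assert cos(P[:, trial] @ xt) - current <= add_penalty + 1e-9, (
            f"candidate {i} should have been added"
        )
    if len(support) > 1:
        for i in support:
            trial = [j for j in support if j != i]
            xt, _ = nnls(P[:, trial], y)
            assert current - cos(P[:, trial] @ xt) > remove_penalty - 1e-9, (
                f"signature {i} should have been pruned"
            )


# --- exact statistics --------------------------------------------------------


def fisher_exact_oracle(n11, n10, n01, n00) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    from math import comb

    r1, r2 = n11 + n10, n01 + n00
    c1 = n11 + n01
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, n11) * comb(r2, c1 - n11) / denom
    p = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = comb(r1, k) * comb(r2, c1 - k) / denom
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return min(p, 1.0)


def ranksum_permutation_oracle(x, y) -> float:
    """Two-sided rank-sum p over all group assignments (midranks for ties)."""
    import scipy.stats

    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n = len(x)
    mean_w = n * (len(pooled) + 1) / 2.0
    w_obs = ranks[:n].sum()
    hits = total = 0
    for comb_idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        w = ranks[list(comb_idx)].sum()
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            hits += 1
    return hits / total


def bh_oracle(pvals):
    """Hand application of the step-up rule."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
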