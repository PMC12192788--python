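"""Independent brute-force oracles used to verify the implementation.

Each oracle recomputes a quantity from its definition by exhaustive
enumeration (or exact rational arithmetic), sharing no code with the
implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np

from rohscan.data import HET, MISSING
from rohscan.detect import RunConfig, TargetState


# ---------------------------------------------------------------------------
# consecutive-run detection
# ---------------------------------------------------------------------------

def _marker_class(g: int, target: TargetState) -> str:
    if g == MISSING:
        return "missing"
    is_het = g == HET
    if target == TargetState.HETEROZYGOUS:
        return "target" if is_het else "opposite"
    return "opposite" if is_het else "target"


def brute_force_runs(genotypes, positions, config: RunConfig):
    """Reference run detection by exhaustive interval checking.

    Semantics of the consecutive method: scanning left to right, each run
    is the longest interval starting at the current leftmost target-state
    marker that satisfies the gap and allowance constraints, trimmed back
    to its last target-state marker; the scan resumes after the untrimmed
    block.  Kept runs must span >= min_snps markers and >= min_length_bp
    base pairs.

    For every start marker i, the validity of *each* candidate interval
    [i, j] is evaluated from its definition (total opposite/missing counts
    and the largest adjacent gap inside the interval, recomputed from
    position i), not by the scanner's incremental early-terminating loop.

    Returns a set of (start_bp, end_bp, n_snps, n_opposite, n_missing).
    """
    cls = np.array([_marker_class(int(g), config.target_state)
                    for g in genotypes])
    pos = np.asarray(positions, dtype=np.int64)
    n = len(cls)
    is_target = cls == "target"
    is_opp = (cls == "opposite").astype(np.int64)
    is_mis = (cls == "missing").astype(np.int64)
    gaps = np.diff(pos)

    out = set()
    s = 0
    while s < n:
        targets = np.flatnonzero(is_target[s:])
        if not len(targets):
            break
        i = s + int(targets[0])
        # criteria over all intervals [i, j], recomputed from scratch:
        # valid[k] <=> interval [i, i+k] obeys both allowances and the gap cap
        opp_tot = np.cumsum(is_opp[i:])
        mis_tot = np.cumsum(is_mis[i:])
        if i < n - 1:
            max_gap_in = np.concatenate(
                [[0], np.maximum.accumulate(gaps[i:])])
        else:
            max_gap_in = np.array([0])
        valid = ((opp_tot <= config.max_opposite)
                 & (mis_tot <= config.max_missing)
                 & (max_gap_in <= config.max_gap_bp))
        bad = np.flatnonzero(~valid)
        j = i + (int(bad[0]) - 1 if len(bad) else n - 1 - i)
        # trim to last target-state marker
        jt = i + int(np.flatnonzero(is_target[i:j + 1])[-1])
        n_snps = jt - i + 1
        length = int(pos[jt] - pos[i])
        if n_snps >= config.min_snps and length >= config.min_length_bp:
            opp = int(is_opp[i:jt + 1].sum())
            mis = int(is_mis[i:jt + 1].sum())
            out.add((int(pos[i]), int(pos[jt]), n_snps, opp, mis))
        s = j + 1
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by rational enumeration
# ---------------------------------------------------------------------------

def hwe_enumeration_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value via full enumeration with exact rationals.

    Conditional on n genotypes and the minor-allele count m, the number of
    configurations with h heterozygotes is n! / (a! h! b!) * 2^h with
    a=(m-h)/2 minor homozygotes and b the rest; the two-sided p sums the
    normalized weights of all h whose weight <= the observed one.
    """
    n = n_aa + n_ab + n_bb
    m = 2 * min(n_aa, n_bb) + n_ab
    if m == 0:
        return 1.0
    weights = {}
    for h in range(m % 2, m + 1, 2):
        a = (m - h) // 2
        b = n - a - h
        if b < 0:
            continue
        # multinomial count n!/(a! h! b!) times 2^h phased arrangements
        weights[h] = Fraction(
            comb(n, a) * comb(n - a, h) * 2 ** h)
    total = sum(weights.values())
    obs = weights[n_ab]
    p = sum(w for w in weights.values() if w <= obs) / total
    return float(p)


# ---------------------------------------------------------------------------
# exact Wilcoxon rank-sum by labeling enumeration
# ---------------------------------------------------------------------------

def wilcoxon_enumeration_pvalue(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all C(n_x+n_y, n_x)
    assignments of the pooled ranks to group x (untied data)."""
    x = list(map(float, x))
    y = list(map(float, y))
    n_x, n_y = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    obs_u = sum(1 for xi in x for yi in y if xi > yi)
    us = []
    ranks = range(n_x + n_y)
    for subset in combinations(ranks, n_x):
        u = sum(subset) - n_x * (n_x - 1) // 2
        us.append(u)
    us = np.array(us)
    p_le = np.mean(us <= obs_u)
    p_ge = np.mean(us >= obs_u)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# island machinery
# ---------------------------------------------------------------------------

def stabbing_incidence(runs_rows, positions_by_chrom, sample_ids):
    """Per-SNP incidence by direct point-in-interval counting.

    ``runs_rows`` is an iterable of (sample_id, chromosome, start, end);
    ``positions_by_chrom`` maps chromosome -> list of positions.  Returns
    {(chromosome, position): count of distinct individuals covering it}.
    """
    cover = {}
    for chrom, plist in positions_by_chrom.items():
        for p in plist:
            owners = set()
            for sid, c, s, e in runs_rows:
                if sid in sample_ids and c == chrom and s <= p <= e:
                    owners.add(sid)
            cover[(chrom, p)] = len(owners)
    return cover


def sort_based_selection(values, pct):
    """Top-pct selection incl. threshold ties, via a full sort and ranks."""
    values = list(map(float, values))
    k = -(-len(values) * pct // 100)  # ceil
    k = max(int(k), 1)
    thr = sorted(values, reverse=True)[k - 1]
    return [v >= thr for v in values], thr


def rle_islands(flags, chroms, min_snps):
    """Run-length-encoding aggregation of selected flags per chromosome."""
    blocks = []
    cur = None
    for i, (f, c) in enumerate(zip(flags, chroms)):
        if f and cur is not None and c == cur[0]:
            cur = (c, cur[1], i)
        elif f:
            if cur is not None and cur[2] - cur[1] + 1 >= min_snps:
                blocks.append(cur)
            cur = (c, i, i)
        else:
            if cur is not None and cur[2] - cur[1] + 1 >= min_snps:
                blocks.append(cur)
            cur = None
    if cur is not None and cur[2] - cur[1] + 1 >= min_snps:
        blocks.append(cur)
    return blocks


def all_pairs_overlaps(intervals_a, intervals_b):
    """Quadratic interval intersection; 1-based inclusive coordinates.

    Each interval is (chromosome, start, end, name); returns the set of
    (name_a, name_b, overlap_bp) for every pair with positive overlap.
    """
    out = set()
    for ca, sa, ea, na in intervals_a:
        for cb, sb, eb, nb in intervals_b:
            if ca != cb:
                continue
            ov = min(ea, eb) - max(sa, sb) + 1
            if ov > 0:
                out.add((na, nb, ov))
    return out


# ---------------------------------------------------------------------------
# summary aggregation
# ---------------------------------------------------------------------------

def direct_animal_stats(run_lengths_by_sample, thresholds):
    """Counts and sums per (sample, >t class) by direct iteration."""
    out = {}
    for sid, lengths in run_lengths_by_sample.items():
        for t in thresholds:
            sel = [L for L in lengths if L > t]
            out[(sid, t)] = (len(sel), sum(sel))
    return out
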