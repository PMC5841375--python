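"""Evaluation statistics: subsampling, beta-diversity, Mantel, ICC.

Everything needed to score a pipeline run against a gold standard:
rarefaction-style subsampling to a common depth, Bray-Curtis and
unweighted/weighted UniFrac distance matrices, Mantel correlation with
permutation p-values and bootstrap standard errors, per-genus Spearman
correlations, prevalence filtering and the one-way random-effects ICC
over technical replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode

from .seqio import OTUTable
from .taxonomy import RANKS, TaxonomyCall


@dataclass
class ReplicateDesign:
    """sample_id -> (subject_id, condition_label, replicate_index)."""

    entries: dict[str, tuple[str, str, int]]

    def groups(self) -> dict[tuple[str, str], list[str]]:
        out: dict[tuple[str, str], list[str]] = {}
        for sid, (subj, cond, _rep) in self.entries.items():
            out.setdefault((subj, cond), []).append(sid)
        return out


def subsample_counts(table: OTUTable, depth: int, seed: int = 0) -> OTUTable:
    """Draw ``depth`` reads per sample without replacement (hypergeometric).

    Samples with fewer than ``depth`` reads are dropped with a warning.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    kept = []
    for sid in table.sample_ids:
        row = table.counts.loc[sid].to_numpy()
        total = int(row.sum())
        if total < depth:
            warnings.warn(f"sample {sid} has {total} < depth {depth}; dropped")
            continue
        if total == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
        kept.append(sid)
    df = pd.DataFrame(rows, index=kept, columns=table.otu_ids, dtype=np.int64)
    return OTUTable(df, dict(table.otu_metadata))


def bray_curtis(table: OTUTable) -> DistanceMatrix:
    """BC(i,j) = sum|x-y| / sum(x+y); two all-zero samples are distance 0."""
    X = table.counts.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("bray_curtis needs at least 2 samples")
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        tot = (X[i] + X[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1), 0.0)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return DistanceMatrix(D, table.sample_ids)


def _branches(tree: TreeNode, otu_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and per-branch OTU-descendant indicator matrix."""
    tip_index = {o: k for k, o in enumerate(otu_ids)}
    tips_in_tree = {t.name for t in tree.tips()}
    missing = set(otu_ids) - tips_in_tree
    if missing:
        raise ValueError(f"OTUs absent from tree: {sorted(missing)}")
    lengths = []
    members = []
    for node in tree.postorder(include_self=False):
        if node.length is None:
            node.length = 0.0
        below = np.zeros(len(otu_ids), dtype=bool)
        if node.is_tip():
            if node.name in tip_index:
                below[tip_index[node.name]] = True
        else:
            for t in node.tips():
                if t.name in tip_index:
                    below[tip_index[t.name]] = True
        lengths.append(node.length)
        members.append(below)
    return np.asarray(lengths, dtype=float), np.stack(members)


def unifrac(
    table: OTUTable,
    tree: TreeNode,
    weighted: bool = False,
    normalized: bool = True,
) -> DistanceMatrix:
    """Unweighted or weighted UniFrac over all sample pairs.

    Unweighted: unique branch length / observed branch length. Weighted:
    sum_b l_b |p_A(b) - p_B(b)|, divided by sum_b l_b (p_A(b) + p_B(b))
    when ``normalized``. The tree is midpoint-rooted first if its root is
    not already bifurcating.
    """
    work = tree
    if len(work.children) != 2:
        work = work.copy().root_at_midpoint()
    L, M = _branches(work, table.otu_ids)
    X = table.counts.to_numpy(dtype=float)  # samples x otus
    totals = X.sum(axis=1)
    totals_safe = np.where(totals > 0, totals, 1.0)
    sids = table.sample_ids
    n = len(sids)
    D = np.zeros((n, n))
    if not weighted:
        P = (X @ M.T.astype(float)) > 0  # samples x branches
        Lw = L[None, :]
        s = (Lw * P).sum(axis=1)  # per-sample observed branch length
        A = (P * Lw) @ P.T        # shared observed length
        for i in range(n):
            for j in range(i + 1, n):
                union = s[i] + s[j] - A[i, j]
                xor = s[i] + s[j] - 2 * A[i, j]
                D[i, j] = D[j, i] = xor / union if union > 0 else 0.0
    else:
        Wp = (X / totals_safe[:, None]) @ M.T.astype(float)  # samples x branches
        for i in range(n):
            for j in range(i + 1, n):
                num = (L * np.abs(Wp[i] - Wp[j])).sum()
                if normalized:
                    den = (L * (Wp[i] + Wp[j])).sum()
                    D[i, j] = D[j, i] = num / den if den > 0 else 0.0
                else:
                    D[i, j] = D[j, i] = num
    return DistanceMatrix(D, sids)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    bootstrap_se: float | None = None


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = rankdata(x)
        y = rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 1000,
    n_boot: int = 0,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation of two distance matrices over the same samples.

    p = (1 + #{permuted r >= observed r}) / (1 + n_perm), permuting one
    matrix's labels jointly on rows and columns. The optional bootstrap SE
    resamples sample labels with replacement and recomputes r on the
    induced submatrices (self-pairs of a duplicated sample excluded).
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share their label sets")
    order = list(d1.ids)
    M1 = np.array(d1.data, dtype=float)
    M2 = np.array(d2.filter(order).data, dtype=float)
    n = M1.shape[0]
    r_obs = _corr(_upper(M1), _upper(M2), method)
    rng = np.random.default_rng(seed)
    hits = 0
    v1 = _upper(M1)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _corr(v1, _upper(M2[np.ix_(perm, perm)]), method)
        if r_p >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    se = None
    if n_boot > 0:
        rs = []
        iu = np.triu_indices(n, k=1)
        for _ in range(n_boot):
            ix = rng.integers(0, n, size=n)
            keep = ix[iu[0]] != ix[iu[1]]  # drop duplicated-sample self pairs
            b1 = M1[np.ix_(ix, ix)][iu][keep]
            b2 = M2[np.ix_(ix, ix)][iu][keep]
            if b1.size >= 3:
                rs.append(_corr(b1, b2, method))
        se = float(np.std(rs, ddof=1)) if len(rs) > 1 else None
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, bootstrap_se=se)


def icc_oneway(values: dict[str, float], design: ReplicateDesign) -> float:
    """One-way random-effects ICC over technical-replicate groups.

    ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW) with the unbalanced-adjusted
    mean group size k0; the raw estimate is returned unclipped. Groups with
    a single usable replicate are excluded; fewer than 2 usable groups is
    an error.
    """
    groups = []
    for _key, sids in design.groups().items():
        obs = [values[s] for s in sids if s in values]
        if len(obs) >= 2:
            groups.append(np.asarray(obs, dtype=float))
    G = len(groups)
    if G < 2:
        raise ValueError("icc_oneway needs at least 2 groups with >= 2 replicates")
    N = sum(len(g) for g in groups)
    grand = sum(g.sum() for g in groups) / N
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (G - 1)
    msw = ssw / (N - G)
    k0 = (N - sum(len(g) ** 2 for g in groups) / N) / (G - 1)
    denom = msb + (k0 - 1) * msw
    if denom == 0:
        return 0.0
    return float((msb - msw) / denom)


def prevalence_filter(table: OTUTable, min_prev: float) -> OTUTable:
    """Keep features present in strictly more than min_prev * n samples."""
    if not (0 <= min_prev <= 1):
        raise ValueError("min_prev must be in [0, 1]")
    n = len(table.sample_ids)
    present = (table.counts > 0).sum(axis=0)
    keep = present.index[present > min_prev * n]
    meta = {o: m for o, m in table.otu_metadata.items() if o in set(keep)}
    return OTUTable(table.counts[list(keep)], meta)


def per_taxon_spearman(tableA: OTUTable, tableB: OTUTable) -> dict[str, float]:
    """Per-feature Spearman correlation of relative abundances across samples.

    Features absent from one table are scored against a zero vector, which
    yields 0 (degenerate rank correlation reported as 0).
    """
    samples = [s for s in tableA.sample_ids if s in set(tableB.sample_ids)]
    if not samples:
        raise ValueError("tables share no samples")
    A = tableA.counts.loc[samples]
    B = tableB.counts.loc[samples]
    relA = A.div(A.sum(axis=1).replace(0, 1), axis=0)
    relB = B.div(B.sum(axis=1).replace(0, 1), axis=0)
    out: dict[str, float] = {}
    for taxon in sorted(set(A.columns) | set(B.columns)):
        x = relA[taxon].to_numpy() if taxon in relA else np.zeros(len(samples))
        y = relB[taxon].to_numpy() if taxon in relB else np.zeros(len(samples))
        out[taxon] = _corr(x, y, "spearman")
    return out


def collapse_to_genus(
    table: OTUTable, calls: dict[str, TaxonomyCall]
) -> OTUTable:
    """Sum counts over OTUs sharing an assigned genus.

    OTUs unclassified at genus level are pooled into
    ``unclassified_<deepest assigned label>`` bins, preserving the grand
    total; the bin mass is the unclassified-at-genus read fraction.
    """
    genus_rank = RANKS.index("genus")
    col_map: dict[str, str] = {}
    for otu_id in table.otu_ids:
        call = calls[otu_id]
        if call.assigned_rank is None or call.unclassified:
            col_map[otu_id] = "unclassified_root"
        elif RANKS.index(call.assigned_rank) >= genus_rank:
            col_map[otu_id] = call.lineage[genus_rank]
        else:
            deepest = call.lineage[RANKS.index(call.assigned_rank)]
            col_map[otu_id] = f"unclassified_{deepest}"
    collapsed = table.counts.T.groupby(
        table.counts.columns.map(col_map)
    ).sum().T
    return OTUTable(collapsed)


def unclassified_fraction(genus_table: OTUTable) -> float:
    """Fraction of reads in unclassified-at-genus bins of a collapsed table."""
    total = genus_table.grand_total()
    if total == 0:
        return 0.0
    uncls = [c for c in genus_table.otu_ids if c.startswith("unclassified_")]
    return float(genus_table.counts[uncls].to_numpy().sum()) / total
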