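"""Diversity, ordination, permutation tests, enrichment, and the PLS
path model with direct/indirect/total effects.

Shannon diversity is in nats (natural log).  PERMANOVA uses Anderson's
pseudo-F on squared dissimilarities with seeded raw-label permutations
and p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  The PLS path model
follows the classic mode-A / centroid-scheme algorithm on the fixed
inner DAG  PAH -> bacteria,  PAH -> virus,  bacteria -> virus;  the
indirect PAH->virus effect is the product of the two direct effects on
the mediated path and the total effect is direct + indirect, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("dissimilarities must be nonnegative")


@dataclass
class PathModel:
    """Fitted inner path model on standardized latent scores."""

    direct: dict[tuple[str, str], float]
    indirect: dict[tuple[str, str], float]
    total: dict[tuple[str, str], float]
    scores: pd.DataFrame
    n_iter: int
    boot_ci: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    boot_p: dict[tuple[str, str], float] = field(default_factory=dict)


def shannon(counts: Sequence[float]) -> float:
    """Shannon index H = -sum p ln p over nonzero proportions (nats)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero counts")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def pielou_evenness(counts: Sequence[float]) -> float:
    """J = H / ln(S_observed); undefined for a single taxon."""
    c = np.asarray(counts, dtype=float)
    s = int((c > 0).sum())
    if s < 2:
        raise ValueError("evenness undefined for fewer than 2 taxa")
    return shannon(c) / np.log(s)


def rarefy(counts: Sequence[int], depth: int, seed: int) -> np.ndarray:
    """Subsample without replacement to exactly ``depth`` sequences."""
    c = np.asarray(counts, dtype=np.int64)
    total = int(c.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(c, depth)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """BC(x, y) = sum|x - y| / sum(x + y) for nonnegative vectors."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("vectors must be nonnegative")
    denom = float((a + b).sum())
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(a - b).sum() / denom)


def bray_curtis_matrix(table: pd.DataFrame) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis over the rows of a samples x features table."""
    ids = list(table.index)
    x = table.to_numpy(dtype=float)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(x[i], x[j])
    return DissimilarityMatrix(ids, d)


def pcoa(dm: DissimilarityMatrix, n_axes: int | None = None):
    """Principal coordinate analysis by Gower double-centering.

    Axes are ordered by eigenvalue; axes with non-positive eigenvalues
    are reported in the eigenvalue vector but their coordinates are
    dropped.  Sign convention: the first nonzero loading of each axis
    is positive.
    """
    n = len(dm.ids)
    a = -0.5 * dm.d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, j] = -col
    if n_axes is not None:
        coords = coords[:, :n_axes]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dm.ids, columns=cols), eigvals


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Anderson's pseudo-F and R^2 from squared dissimilarities."""
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dm: DissimilarityMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(pseudo-F, R^2, p) with seeded raw-label permutations."""
    labels = np.asarray(groups)
    if len(labels) != len(dm.ids):
        raise ValueError("groups must match matrix ids")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    d2 = dm.d**2
    f_obs, r2 = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f_perm, _ = _pseudo_f(d2, perm)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(f_obs), float(r2), float(p)


def dispersion_test(
    dm: DissimilarityMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Homogeneity of multivariate dispersions (betadisper-style).

    Distances from each point to its group centroid in PCoA space are
    compared by one-way ANOVA F, with a label-permutation p-value
    (centroids recomputed per permutation).
    """
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    coords, _ = pcoa(dm)
    x = coords.to_numpy()

    def group_distances(lab: np.ndarray) -> list[np.ndarray]:
        out = []
        for g in np.unique(lab):
            pts = x[lab == g]
            centroid = pts.mean(axis=0)
            out.append(np.linalg.norm(pts - centroid, axis=1))
        return out

    f_obs = stats.f_oneway(*group_distances(labels)).statistic
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f_perm = stats.f_oneway(*group_distances(perm)).statistic
        if f_perm >= f_obs:
            hits += 1
    return float(f_obs), (1 + hits) / (1 + n_perm)


def wilcoxon_bh(
    feature_matrix: pd.DataFrame, groups: Sequence
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum with BH adjustment.

    Constant features get p = 1 and are flagged rather than erroring,
    so screens over sparse tables do not abort.
    """
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly 2 groups required")
    mask = labels == uniq[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    rows = []
    for feat in feature_matrix.columns:
        x = feature_matrix[feat].to_numpy(dtype=float)
        a, b = x[mask], x[~mask]
        if np.all(x == x[0]):
            rows.append((feat, np.nan, 1.0, True))
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((feat, float(res.statistic), float(res.pvalue), False))
    out = pd.DataFrame(rows, columns=["feature", "W", "p", "constant"]).set_index(
        "feature"
    )
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def enrich_features(
    values: pd.DataFrame,
    groups: Sequence,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Group-enrichment screen on log10 relative abundance.

    Per feature, OLS of y = log10(relative abundance + half the global
    minimum nonzero relative abundance) on a group indicator; BH across
    features; a feature is enriched in the group its coefficient points
    to when q < q_max.
    """
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly 2 groups required")
    for g in uniq:
        if (labels == g).sum() < 3:
            raise ValueError("need >= 3 samples per group")
    totals = values.sum(axis=1)
    totals[totals == 0] = 1.0
    rel = values.div(totals, axis=0)
    nonzero = rel.values[rel.values > 0]
    pseudo = nonzero.min() / 2 if len(nonzero) else 0.5
    y_all = np.log10(rel + pseudo)
    indicator = (labels == uniq[1]).astype(float)
    rows = []
    for feat in values.columns:
        y = y_all[feat].to_numpy()
        if np.all(y == y[0]):
            rows.append((feat, 0.0, 1.0))
            continue
        res = stats.linregress(indicator, y)
        rows.append((feat, float(res.slope), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["feature", "coefficient", "p"]).set_index(
        "feature"
    )
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched_group"] = np.where(
        out["q"] < q_max, np.where(out["coefficient"] > 0, uniq[1], uniq[0]), None
    )
    return out


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided t-test p-value."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired observations")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def indirect_effect(direct_a_to_m: float, direct_m_to_b: float) -> float:
    """Indirect effect along a single mediated path (product rule)."""
    return direct_a_to_m * direct_m_to_b


_EDGES = (("PAH", "bacteria"), ("PAH", "virus"), ("bacteria", "virus"))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def _pls_scores(
    blocks: dict[str, np.ndarray], tol: float, max_iter: int
) -> tuple[dict[str, np.ndarray], int]:
    """Mode-A outer estimation with the centroid inner scheme."""
    names = list(blocks)
    adjacency = {
        "PAH": ["bacteria", "virus"],
        "bacteria": ["PAH", "virus"],
        "virus": ["PAH", "bacteria"],
    }
    n = next(iter(blocks.values())).shape[0]
    weights = {b: np.ones(blocks[b].shape[1]) for b in names}

    def latent(b: str, w: dict[str, np.ndarray]) -> np.ndarray:
        y = blocks[b] @ w[b]
        sd = y.std(ddof=0)
        return y / sd if sd > 0 else y

    for it in range(1, max_iter + 1):
        scores = {b: latent(b, weights) for b in names}
        new_weights = {}
        for b in names:
            inner = np.zeros(n)
            for other in adjacency[b]:
                sign = np.sign(np.corrcoef(scores[b], scores[other])[0, 1]) or 1.0
                inner += sign * scores[other]
            w = blocks[b].T @ inner / n  # mode A
            norm = np.linalg.norm(w)
            new_weights[b] = w / norm if norm > 0 else w
        delta = max(
            np.max(np.abs(np.abs(new_weights[b]) - np.abs(weights[b]))) for b in names
        )
        weights = new_weights
        if delta < tol:
            return {b: latent(b, weights) for b in names}, it
    raise RuntimeError(
        f"PLS-PM outer estimation did not converge in {max_iter} iterations "
        f"(last weight delta {delta:.3e})"
    )


def _path_coefficients(scores: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    # latent scores are centered with unit variance, so OLS slopes are
    # the standardized path coefficients directly
    pah, bact, vir = scores["PAH"], scores["bacteria"], scores["virus"]
    b_pb = float(np.corrcoef(pah, bact)[0, 1])
    x = np.column_stack([pah, bact])
    beta = np.linalg.lstsq(x, vir, rcond=None)[0]
    return {
        ("PAH", "bacteria"): b_pb,
        ("PAH", "virus"): float(beta[0]),
        ("bacteria", "virus"): float(beta[1]),
    }


def plspm_fit(
    pah_block: pd.DataFrame,
    bacteria_block: pd.DataFrame,
    virus_block: pd.DataFrame,
    n_boot: int = 499,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PathModel:
    """PLS path model PAH -> bacteria -> virus (plus direct PAH -> virus).

    Blocks are samples x manifest variables (standardized internally);
    latent scores come from mode-A outer estimation with the centroid
    inner scheme, path coefficients from least squares on the
    standardized scores.  indirect(PAH, virus) = direct(PAH, bacteria)
    * direct(bacteria, virus) and total = direct + indirect hold
    exactly by construction.  Bootstrap percentile intervals (and a
    two-sided sign-based bootstrap p) use ``seed``.
    """
    idx = pah_block.index
    if not (bacteria_block.index.equals(idx) and virus_block.index.equals(idx)):
        raise ValueError("blocks must share the same sample index")
    if len(idx) < 10:
        raise ValueError("need >= 10 samples")
    raw = {
        "PAH": _standardize(pah_block.to_numpy(dtype=float)),
        "bacteria": _standardize(bacteria_block.to_numpy(dtype=float)),
        "virus": _standardize(virus_block.to_numpy(dtype=float)),
    }

    def fit_once(blocks: dict[str, np.ndarray]) -> tuple[dict, dict, int]:
        scores, n_iter = _pls_scores(blocks, tol, max_iter)
        # Orientation convention: the exogenous PAH latent follows its
        # first manifest variable; endogenous latents are oriented to
        # correlate nonnegatively with the PAH latent.  With
        # ordination-derived manifests the latent direction is not
        # identifiable (PCoA axes are sign-arbitrary), so only
        # magnitudes and relative path signs carry meaning; this
        # convention makes them reproducible.
        r = np.corrcoef(scores["PAH"], blocks["PAH"][:, 0])[0, 1]
        if r < 0:
            scores["PAH"] = -scores["PAH"]
        for b in ("bacteria", "virus"):
            if np.corrcoef(scores[b], scores["PAH"])[0, 1] < 0:
                scores[b] = -scores[b]
        direct = _path_coefficients(scores)
        return direct, scores, n_iter

    direct, scores, n_iter = fit_once(raw)
    indirect = {
        ("PAH", "virus"): indirect_effect(
            direct[("PAH", "bacteria")], direct[("bacteria", "virus")]
        )
    }
    total = {
        ("PAH", "bacteria"): direct[("PAH", "bacteria")],
        ("bacteria", "virus"): direct[("bacteria", "virus")],
        ("PAH", "virus"): direct[("PAH", "virus")] + indirect[("PAH", "virus")],
    }
    boot_ci: dict[tuple[str, str], tuple[float, float]] = {}
    boot_p: dict[tuple[str, str], float] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws: dict[tuple[str, str], list[float]] = {e: [] for e in _EDGES}
        n = len(idx)
        for _ in range(n_boot):
            rows = rng.integers(0, n, size=n)
            blocks_b = {b: _standardize(raw[b][rows]) for b in raw}
            try:
                d_b, _, _ = fit_once(blocks_b)
            except RuntimeError:
                continue
            for e in _EDGES:
                draws[e].append(d_b[e])
        for e in _EDGES:
            vals = np.asarray(draws[e])
            if len(vals):
                boot_ci[e] = (
                    float(np.percentile(vals, 2.5)),
                    float(np.percentile(vals, 97.5)),
                )
                frac = min((vals <= 0).mean(), (vals >= 0).mean())
                boot_p[e] = float(min(1.0, 2 * frac))
    score_df = pd.DataFrame(scores, index=idx)
    return PathModel(direct, indirect, total, score_df, n_iter, boot_ci, boot_p)
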