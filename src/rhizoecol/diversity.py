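"""Alpha diversity, Bray-Curtis beta diversity, ordination and group tests.

Alpha indices are the three standard amplicon summaries (observed richness,
bias-corrected Chao1, Shannon entropy in nats).  Beta diversity is
Bray-Curtis with principal-coordinates ordination; group structure is tested
with a one-way PERMANOVA (Anderson's distance-based pseudo-F, label
permutations) and a within- vs between-group similarity contrast.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import OrdinationResults
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import FeatureTable

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "PermanovaResult",
    "similarity_contrast",
    "anova_tukey",
]


def _chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_diversity(table: FeatureTable, bias_corrected_chao1: bool = True) -> pd.DataFrame:
    """Per-sample richness, Chao1 and Shannon (natural log).

    Chao1 defaults to the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)),
    which stays finite when no doubletons are observed.  Empty samples get
    zeros with a warning.
    """
    rows = {}
    for s in table.sample_ids:
        counts = table.counts.loc[s].to_numpy()
        total = counts.sum()
        if total == 0:
            warnings.warn(f"sample {s!r} is empty; reporting zero diversity")
            rows[s] = (0, 0.0, 0.0)
            continue
        present = counts[counts > 0]
        p = present / total
        shannon = float(-(p * np.log(p)).sum())
        rows[s] = (len(present), _chao1(counts, bias_corrected_chao1), shannon)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["richness", "chao1", "shannon"]
    ).rename_axis("sample_id")


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = sum|x-y| / sum(x+y)."""
    if (table.sample_totals == 0).any():
        empty = list(table.sample_totals[table.sample_totals == 0].index)
        raise ValueError(f"all-zero sample(s): {empty}")
    mat = squareform(pdist(table.counts.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(mat, ids=table.sample_ids)


def pcoa(dm: DistanceMatrix) -> OrdinationResults:
    """Classical metric MDS on -0.5 * D^2 after double centring.

    Negative eigenvalues (non-Euclidean part of Bray-Curtis) are reported,
    not corrected away; axes are ordered by decreasing eigenvalue.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        return _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squares from squared distances."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    metadata: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with label permutations.

    Pseudo-F follows the distance-based partitioning: SS_total from all
    pairs, SS_within from within-group pairs; p includes the observed
    statistic in its reference set, so p >= 1/(n_permutations + 1).
    """
    labels = metadata.loc[list(dm.ids)].to_numpy()
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        small = groups[counts < 2]
        raise ValueError(f"group(s) with fewer than 2 samples: {list(small)}")
    n, a = len(labels), len(groups)
    d2 = np.asarray(dm.data) ** 2

    def f_stat(lab: np.ndarray) -> float:
        ss_t, ss_w = _permanova_ss(d2, lab)
        ss_b = ss_t - ss_w
        return (ss_b / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(labels)
    ss_t, ss_w = _permanova_ss(d2, labels)
    r2 = (ss_t - ss_w) / ss_t
    rng = np.random.default_rng(seed)
    exceed = sum(
        f_stat(rng.permutation(labels)) >= f_obs for _ in range(n_permutations)
    )
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations, seed)


def similarity_contrast(
    dm: DistanceMatrix, metadata: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within- and between-group similarity (1 - Bray-Curtis) distributions.

    Every unordered sample pair lands in exactly one set: "within:g" for
    same-group pairs, "between:g|h" otherwise.  All pairwise set contrasts
    are tested with a two-sided Wilcoxon rank-sum test and BH-corrected.

    Returns (sets, tests): per-set summaries and the contrast table.
    """
    labels = metadata.loc[list(dm.ids)].to_numpy()
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("similarity contrast needs at least two groups")
    sets: dict[str, list[float]] = {}
    mat = np.asarray(dm.data)
    n = len(labels)
    for i, j in itertools.combinations(range(n), 2):
        sim = 1.0 - mat[i, j]
        gi, gj = labels[i], labels[j]
        if gi == gj:
            key = f"within:{gi}"
        else:
            a, b = sorted((gi, gj))
            key = f"between:{a}|{b}"
        sets.setdefault(key, []).append(sim)
    summary = pd.DataFrame(
        {
            "set": list(sets),
            "n_pairs": [len(v) for v in sets.values()],
            "median_similarity": [float(np.median(v)) for v in sets.values()],
            "mean_similarity": [float(np.mean(v)) for v in sets.values()],
        }
    ).set_index("set")
    rows = []
    for s1, s2 in itertools.combinations(sorted(sets), 2):
        res = stats.ranksums(sets[s1], sets[s2])
        rows.append((s1, s2, float(res.statistic), float(res.pvalue)))
    tests = pd.DataFrame(rows, columns=["set_a", "set_b", "statistic", "p"])
    if len(tests):
        tests["q"] = multipletests(tests["p"], method="fdr_bh")[1]
    return summary, tests


def anova_tukey(values: pd.Series, metadata: pd.Series) -> dict:
    """One-way ANOVA across groups plus Tukey HSD pairwise comparisons."""
    common = values.index.intersection(metadata.index)
    vals = values.loc[common].to_numpy(dtype=float)
    labels = metadata.loc[common].to_numpy()
    groups = [vals[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    degenerate = all(np.ptp(g) == 0 for g in groups)
    if degenerate:
        warnings.warn("zero within-group variance everywhere; ANOVA degenerate")
        return {"f": np.nan, "p": np.nan, "degenerate": True, "tukey": None}
    f, p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(vals, labels)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {"f": float(f), "p": float(p), "degenerate": False, "tukey": tukey_df}
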