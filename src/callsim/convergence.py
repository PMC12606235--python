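"""Pre/post-introduction convergence tests.

Changes in dyadic call similarity are measured by fitting two independent
caller DFAs — residents plus focal bats recorded *before* introduction,
and the same residents plus the focal bats recorded *after* — extracting
each DFA's normalized similarity matrix, and differencing them.  Three
tests ask whether convergence is concentrated in newly introduced pairs:

* a Mantel test (Spearman correlation between the similarity-change matrix
  and the introduced-pair indicator, permuting bats jointly in rows and
  columns),
* a Gaussian multi-membership regression of the change on the introduced
  flag, and
* permuted DFAs classifying calls to capture site, with the bat (not the
  call) as the unit of permutation and of hold-out, so pseudo-replication
  of calls within bats cannot inflate the group signature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .similarity import (
    SimilarityMatrix,
    _pooled_fit,
    DfaModel,
    fit_dfa,
    centroid_mahalanobis_matrix,
    similarity_from_distances,
)
from .mm import GaussianMultiMembership, MultiMembershipResults


@dataclass
class PrePostDesign:
    """Which bats are residents (recorded once) vs focal (pre and post)."""

    resident_ids: list
    focal_ids: list

    def introduced_indicator(self, site_of: dict) -> pd.DataFrame:
        """1 for cross-site (introduced) pairs, 0 for same-site (familiar)."""
        ids = list(self.resident_ids) + list(self.focal_ids)
        n = len(ids)
        M = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                if a != b and site_of[ids[a]] != site_of[ids[b]]:
                    M[a, b] = 1.0
        return pd.DataFrame(M, index=ids, columns=ids)


@dataclass
class PrePostSimilarity:
    S_pre: SimilarityMatrix
    S_post: SimilarityMatrix
    delta: pd.DataFrame  # S_post - S_pre on the common bats

    def pairs(self) -> pd.DataFrame:
        ids = list(self.delta.index)
        rows = [
            {"bat_i": ids[i], "bat_j": ids[j], "delta_s": self.delta.iloc[i, j]}
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        ]
        return pd.DataFrame(rows)


def pre_post_similarity(
    features_pre: pd.DataFrame,
    features_post: pd.DataFrame,
    design: PrePostDesign,
    floor: float = 0.001,
) -> PrePostSimilarity:
    """Similarity change between two epochs via two independent DFAs.

    Each epoch's table must contain calls for every design bat.  Each DFA is
    normalized by its own maximum centroid distance, so pre and post
    similarities are each on their own (0, 1] scale; the difference mixes
    the two normalizations, which is inherent to the design.
    """
    ids = list(design.resident_ids) + list(design.focal_ids)
    out = []
    for name, tab in (("pre", features_pre), ("post", features_post)):
        present = set(tab["bat_id"])
        missing = [b for b in ids if b not in present]
        if missing:
            raise ValueError(f"{name} epoch is missing bats: {missing}")
        sub = tab[tab["bat_id"].isin(ids)]
        model = fit_dfa(sub)
        D = centroid_mahalanobis_matrix(model)
        out.append(similarity_from_distances(D.loc[ids, ids], floor=floor))
    s_pre, s_post = out
    delta = s_post.S.loc[ids, ids] - s_pre.S.loc[ids, ids]
    return PrePostSimilarity(s_pre, s_post, delta)


@dataclass
class MantelResult:
    statistic: float
    n_perm: int
    p_value: float
    seed: int
    null: np.ndarray
    alternative: str


def _offdiag_upper(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def _spearman(a_ranks, b_ranks):
    a = a_ranks - a_ranks.mean()
    b = b_ranks - b_ranks.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("constant matrix: Spearman correlation undefined")
    return float((a * b).sum() / denom)


def mantel_spearman(
    delta: pd.DataFrame | np.ndarray,
    indicator: pd.DataFrame | np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test with Spearman correlation between two dyadic matrices.

    The null permutes individuals: rows and columns of the indicator matrix
    are permuted jointly, preserving its dyadic structure and value
    multiset.  One-tailed 'greater' by default (the directional prediction
    that introduced pairs converge more); 'less' and 'two-sided' by flag.
    With ``exhaustive=True`` all n! permutations are enumerated and the
    p-value is the exact permutation probability.
    """
    A = delta.to_numpy(dtype=float) if isinstance(delta, pd.DataFrame) else np.asarray(delta, float)
    B = indicator.to_numpy(dtype=float) if isinstance(indicator, pd.DataFrame) else np.asarray(indicator, float)
    n = A.shape[0]
    if A.shape != B.shape or A.shape != (n, n):
        raise ValueError("matrices must be square and conforming")
    if n < 4:
        raise ValueError("need at least 4 individuals")

    a_ranks = rankdata(_offdiag_upper(A))

    def corr_for(perm):
        Bp = B[np.ix_(perm, perm)]
        return _spearman(a_ranks, rankdata(_offdiag_upper(Bp)))

    observed = corr_for(np.arange(n))

    def tail(stat_null, obs):
        if alternative == "greater":
            return stat_null >= obs
        if alternative == "less":
            return stat_null <= obs
        return np.abs(stat_null) >= abs(obs)

    if exhaustive:
        null = np.array(
            [corr_for(np.array(p)) for p in itertools.permutations(range(n))]
        )
        p = float(np.mean(tail(null, observed)))
        n_used = len(null)
    else:
        rng = np.random.default_rng(seed)
        null = np.array([corr_for(rng.permutation(n)) for _ in range(n_perm)])
        p = float((1 + np.sum(tail(null, observed))) / (1 + n_perm))
        n_used = n_perm
    return MantelResult(observed, n_used, p, seed, null, alternative)


def fit_gaussian_mm(
    delta_records: pd.DataFrame,
    mcmc: dict | None = None,
) -> MultiMembershipResults:
    """Regress similarity change on the introduced-pair flag.

    ``delta_records`` needs columns bat_i, bat_j, delta_s, introduced
    (0/1).  Fits the Gaussian multi-membership model
    delta_s ~ alpha + beta * introduced + 0.5 u_i + 0.5 u_j.
    """
    mcmc = dict(mcmc or {})
    records = delta_records.copy()
    records["introduced"] = records["introduced"].astype(float)
    model = GaussianMultiMembership.from_dyads(
        records, ["introduced"], outcome="delta_s"
    )
    res = model.fit(**mcmc)
    res.check_convergence()
    return res


@dataclass
class PdfaResult:
    observed_accuracy: float
    null: np.ndarray
    n_perm: int
    p_value: float
    seed: int


def _site_accuracy_bats_heldout(X, bat_of, site_of_bat):
    """DFA site accuracy with whole bats held out in rotation.

    Equal site priors: count-proportional priors would penalize the
    held-out bat's own site (it always has fewer training calls), biasing
    null accuracy below chance.
    """
    bats = list(site_of_bat)
    correct = 0
    total = 0
    sites = np.array([site_of_bat[b] for b in bat_of])
    for held in bats:
        train = bat_of != held
        if len(np.unique(sites[train])) < 2:
            raise ValueError("holding out a bat removed a whole site")
        classes = np.unique(sites[train])
        centroids, counts, _, cov = _pooled_fit(X[train], sites[train], classes)
        priors = np.full(len(classes), 1 / len(classes))
        model = DfaModel(classes, centroids, cov, priors, counts, [])
        pred = model.predict(X[~train])
        correct += int(np.sum(pred == site_of_bat[held]))
        total += int(np.sum(~train))
    return correct / total


def pdfa_site(
    features: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    site_column: str = "site",
) -> PdfaResult:
    """Permuted DFA for a group (site) signature, calls nested in bats.

    Observed accuracy: classify calls to site with every bat held out in
    rotation (train on the other bats, predict the held-out bat's calls).
    Null: permute the bat-to-site assignment, preserving the number of bats
    per site, and recompute the same rotation accuracy — no permutation
    ever splits one bat's calls across sites.
    """
    need = {"bat_id", site_column}
    if not need.issubset(features.columns):
        raise ValueError(f"features table needs columns {sorted(need)}")
    site_of_bat = (
        features.drop_duplicates("bat_id").set_index("bat_id")[site_column].to_dict()
    )
    per_site = pd.Series(site_of_bat).value_counts()
    if len(per_site) < 2:
        raise ValueError("need at least two sites")
    if per_site.min() < 2:
        raise ValueError("each site needs at least two bats to permute and hold out")

    feat_cols = [
        c for c in features.columns
        if c not in ("bat_id", site_column, "source", "call_index", "epoch")
    ]
    X = features[feat_cols].to_numpy(dtype=float)
    bat_of = features["bat_id"].to_numpy()

    observed = _site_accuracy_bats_heldout(X, bat_of, site_of_bat)

    rng = np.random.default_rng(seed)
    bats = list(site_of_bat)
    labels = np.array([site_of_bat[b] for b in bats])
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = dict(zip(bats, labels[rng.permutation(len(bats))]))
        null[k] = _site_accuracy_bats_heldout(X, bat_of, perm)
    p = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    return PdfaResult(observed, null, n_perm, p, seed)
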