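"""System-level metabolome statistics for the two-pipeline comparison.

Covers the odd-mass abundance statistic RN (the abundance-weighted fraction
of a sample's metabolome carried by odd-nominal-mass molecules — a proxy
for organonitrogen metabolism via the nitrogen rule), per-system abundance
sums, differential-feature selection, the fold-ratio similarity summary,
identified:non-identified ratios among the most abundant features, and a
principal component analysis of replicate abundance profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .chem_mass import nitrogen_parity
from .feature_pipeline import FeatureTable

__all__ = [
    "RNResult",
    "DifferentialResult",
    "RatioSummary",
    "PCAResult",
    "rn_statistic",
    "system_sums",
    "differential_features",
    "ratio_distribution",
    "id_ratio_top_n",
    "pca_features",
    "parse_system_map",
]

DEFAULT_SYSTEM_MAP = {"LC3": "LC", "LC11": "LC", "HC3": "HC", "HC11": "HC"}


@dataclass(frozen=True)
class RNResult:
    sample: str
    subset: str
    rn_percent: float
    odd_abundance_iu: float
    total_abundance_iu: float
    n_features: int


@dataclass
class DifferentialResult:
    """HC/LC differential-feature calls.

    ``per_feature`` has per-system sums, the HC/LC ratio (inf when one side
    is zero), and disjoint enrichment flags."""

    per_feature: pd.DataFrame
    hc_enriched_count: int
    lc_enriched_count: int
    min_abundance_iu: float
    min_ratio: float


@dataclass(frozen=True)
class RatioSummary:
    fraction_similar: float
    fold: float
    n_both_nonzero: int
    n_one_sided: int
    n_both_zero: int


@dataclass
class PCAResult:
    scores: pd.DataFrame        # (sample, replicate) x component
    loadings: pd.DataFrame      # feature x component
    explained_variance_ratio: np.ndarray
    n_features_used: int
    scale: str


def rn_statistic(
    table: FeatureTable,
    sample: str,
    subset: Iterable[str] | Callable[[str], bool] | None = None,
    parity_overrides: Mapping[str, bool] | None = None,
    subset_label: str = "all",
) -> RNResult:
    """Abundance-weighted percentage of odd-nominal-mass features.

    RN = 100 x (sum of per-sample mean abundances of odd-mass features) /
    (sum over all features in the subset).  Parity is called on the
    measured neutral mass; ``parity_overrides`` (feature_id -> odd?) lets
    callers substitute the exact formula parity for annotated features,
    where the nitrogen rule is exact.
    """
    means = table.sample_means()
    if sample not in means.columns:
        raise KeyError(f"unknown sample {sample!r}")
    if subset is None:
        ids = list(means.index)
    elif callable(subset):
        ids = [fid for fid in means.index if subset(fid)]
    else:
        wanted = set(subset)
        ids = [fid for fid in means.index if fid in wanted]
    total = float(means.loc[ids, sample].sum())
    if total <= 0:
        raise ValueError(f"total abundance in sample {sample!r} is zero; RN undefined")
    odd = 0.0
    for fid in ids:
        if parity_overrides is not None and fid in parity_overrides:
            is_odd = bool(parity_overrides[fid])
        else:
            is_odd = nitrogen_parity(float(table.features.at[fid, "neutral_mass_da"])).is_odd
        if is_odd:
            odd += float(means.at[fid, sample])
    return RNResult(
        sample=sample,
        subset=subset_label,
        rn_percent=100.0 * odd / total,
        odd_abundance_iu=odd,
        total_abundance_iu=total,
        n_features=len(ids),
    )


def system_sums(table: FeatureTable, system_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-feature abundance per system: sum of per-sample means over the
    samples mapped to each system (e.g. HC = HC3 + HC11)."""
    system_map = dict(system_map or DEFAULT_SYSTEM_MAP)
    means = table.sample_means()
    unmapped = [s for s in means.columns if s not in system_map]
    if unmapped:
        raise KeyError(f"samples not mapped to a system: {unmapped}")
    out = {}
    for system in dict.fromkeys(system_map.values()):
        samples = [s for s in means.columns if system_map[s] == system]
        out[system] = means[samples].sum(axis=1)
    return pd.DataFrame(out)


def differential_features(
    sums: pd.DataFrame,
    hc: str = "HC",
    lc: str = "LC",
    min_abundance_iu: float = 10_000.0,
    min_ratio: float = 5.0,
) -> DifferentialResult:
    """Features strongly enriched in one system.

    A feature is HC-enriched iff at least one system exceeds the abundance
    gate (strictly above ``min_abundance_iu``) and HC/LC >= ``min_ratio``
    (a zero LC with HC above the gate counts: infinite ratio); LC-enriched
    symmetrically.  The two sets are disjoint for min_ratio > 1.
    """
    hc_ab = sums[hc].to_numpy(float)
    lc_ab = sums[lc].to_numpy(float)
    gate = (hc_ab > min_abundance_iu) | (lc_ab > min_abundance_iu)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lc_ab > 0, hc_ab / np.where(lc_ab > 0, lc_ab, 1.0), np.inf)
        ratio = np.where((lc_ab == 0) & (hc_ab == 0), np.nan, ratio)
    hc_enriched = gate & (ratio >= min_ratio)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_ratio = np.where(hc_ab > 0, lc_ab / np.where(hc_ab > 0, hc_ab, 1.0), np.inf)
        inv_ratio = np.where((lc_ab == 0) & (hc_ab == 0), np.nan, inv_ratio)
    lc_enriched = gate & (inv_ratio >= min_ratio)
    per_feature = pd.DataFrame(
        {
            hc: hc_ab,
            lc: lc_ab,
            "hc_lc_ratio": ratio,
            "hc_enriched": hc_enriched,
            "lc_enriched": lc_enriched,
        },
        index=sums.index,
    )
    return DifferentialResult(
        per_feature=per_feature,
        hc_enriched_count=int(hc_enriched.sum()),
        lc_enriched_count=int(lc_enriched.sum()),
        min_abundance_iu=min_abundance_iu,
        min_ratio=min_ratio,
    )


def ratio_distribution(sums: pd.DataFrame, fold: float = 3.0) -> RatioSummary:
    """Fraction of features whose two-system abundances differ by less than
    ``fold``; only features observed in both systems enter the fraction,
    one-sided features are tallied separately."""
    a = sums.iloc[:, 0].to_numpy(float)
    b = sums.iloc[:, 1].to_numpy(float)
    both = (a > 0) & (b > 0)
    one_sided = ((a > 0) ^ (b > 0))
    hi = np.maximum(a[both], b[both])
    lo = np.minimum(a[both], b[both])
    similar = hi / lo < fold
    fraction = float(similar.mean()) if both.any() else float("nan")
    return RatioSummary(
        fraction_similar=fraction,
        fold=fold,
        n_both_nonzero=int(both.sum()),
        n_one_sided=int(one_sided.sum()),
        n_both_zero=int((~both & ~one_sided).sum()),
    )


def id_ratio_top_n(
    table: FeatureTable, identified_ids: Iterable[str], sample: str, n: int = 200
) -> float:
    """Identified : non-identified ratio among the n most abundant features
    of a sample (per-sample means; ties broken by feature id).  Returns
    ``inf`` when every one of the top n is identified."""
    means = table.sample_means()
    if sample not in means.columns:
        raise KeyError(f"unknown sample {sample!r}")
    if n > len(means):
        raise ValueError(f"n={n} exceeds the {len(means)} features in the table")
    ranked = (
        means[[sample]]
        .reset_index()
        .sort_values([sample, "feature_id"], ascending=[False, True], kind="stable")
        .head(n)
    )
    identified = set(identified_ids)
    n_id = int(ranked["feature_id"].isin(identified).sum())
    n_not = n - n_id
    if n_not == 0:
        return math.inf
    return n_id / n_not


def pca_features(
    table: FeatureTable,
    min_abundance_iu: float = 10_000.0,
    scale: str = "linear",
    n_components: int | None = None,
) -> PCAResult:
    """PCA of replicate abundance profiles.

    Features reaching ``min_abundance_iu`` (per-sample mean) in at least
    one sample are retained; observations are the individual
    sample x replicate abundance vectors.  With ``scale='log'`` abundances
    are log10(x+1)-transformed first.  Variables (features) are
    mean-centered, not variance-scaled: absolute abundance differences are
    the signal of interest.  Components come from singular value
    decomposition of the centered matrix.
    """
    if scale not in ("linear", "log"):
        raise ValueError("scale must be 'linear' or 'log'")
    means = table.sample_means()
    keep = (means >= min_abundance_iu).any(axis=1)
    if int(keep.sum()) < 2:
        raise ValueError("fewer than 2 features pass the abundance gate")
    X = table.abundances.loc[keep.index[keep]].to_numpy(float).T  # obs x features
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 observation columns")
    if scale == "log":
        X = np.log10(X + 1.0)
    max_components = min(X.shape[0] - 1, X.shape[1])
    k = max_components if n_components is None else min(n_components, max_components)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    obs_index = pd.MultiIndex.from_tuples(list(table.abundances.columns), names=["sample", "replicate"])
    return PCAResult(
        scores=pd.DataFrame(scores, index=obs_index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=keep.index[keep], columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_features_used=int(keep.sum()),
        scale=scale,
    )


def parse_system_map(text: str) -> dict[str, str]:
    """Parse ``"HC=HC3,HC11;LC=LC3,LC11"`` into a sample -> system map."""
    mapping: dict[str, str] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"bad system map chunk {chunk!r}")
        system, samples = chunk.split("=", 1)
        for sample in samples.split(","):
            sample = sample.strip()
            if sample:
                mapping[sample] = system.strip()
    if not mapping:
        raise ValueError("empty system map")
    return mapping
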