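"""Aligned LC-MS feature tables: alignment, abundance filtering, shot-noise QC.

A *feature* is one aligned (neutral mass, retention time) signal carrying an
abundance, in instrument units (i.u.), for every (sample, replicate) pair.
Raw per-replicate observations are merged into features by single-linkage
grouping within a mass tolerance (ppm) and a retention-time tolerance
(minutes); features recovered in both electrospray ionization modes are
de-duplicated and flagged.

Replicate scatter of ion-counting detectors is dominated by Poisson shot
noise: an abundance A i.u. corresponds to roughly A / iu_per_ion detected
ions, so the expected relative standard deviation is 1/sqrt(A / iu_per_ion).
The QC report flags each (feature, sample) triplicate whose observed RSD is
within a tolerance factor of that expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_mass import ppm_difference

__all__ = [
    "FeatureTable",
    "FilterReport",
    "QCReport",
    "align_features",
    "filter_low_abundance",
    "expected_shot_noise_rsd",
    "qc_shot_noise",
    "read_feature_table",
    "write_feature_table",
    "read_raw_features",
]

#: instrument units registered per detected ion (1,000 i.u. ~ 80 ions).
DEFAULT_IU_PER_ION = 12.5

RAW_COLUMNS = ["neutral_mass_da", "rt_min", "ion_mode", "sample", "replicate", "abundance_iu"]
ION_MODES = ("positive", "negative", "both")


@dataclass
class FeatureTable:
    """An aligned feature table.

    ``features``: DataFrame indexed by feature_id with columns
    ``neutral_mass_da``, ``rt_min``, ``ion_mode``.
    ``abundances``: DataFrame indexed by feature_id with MultiIndex columns
    (sample, replicate), values in i.u.
    """

    features: pd.DataFrame
    abundances: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.abundances.index):
            raise ValueError("features and abundances must share one feature_id index")
        if self.features.index.has_duplicates:
            raise ValueError("feature_ids must be unique")
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        bad_mode = set(self.features["ion_mode"]) - set(ION_MODES)
        if bad_mode:
            raise ValueError(f"unknown ion modes: {sorted(bad_mode)}")

    @property
    def sample_names(self) -> list[str]:
        return list(dict.fromkeys(self.abundances.columns.get_level_values(0)))

    @property
    def replicate_count(self) -> int:
        counts = {
            len(self.abundances[sample].columns) for sample in self.sample_names
        }
        if len(counts) > 1:
            raise ValueError("replicate count is not uniform across samples")
        return counts.pop() if counts else 0

    def __len__(self) -> int:
        return len(self.features)

    def sample_means(self) -> pd.DataFrame:
        """Per-sample mean abundance over replicates (feature x sample)."""
        return self.abundances.T.groupby(level=0).mean().T[self.sample_names]

    def subset(self, feature_ids) -> "FeatureTable":
        ids = pd.Index(feature_ids)
        return FeatureTable(
            features=self.features.loc[ids].copy(),
            abundances=self.abundances.loc[ids].copy(),
            provenance=self.provenance,
        )

    def to_long(self) -> pd.DataFrame:
        long = self.abundances.stack(level=[0, 1], future_stack=True).rename("abundance_iu").reset_index()
        long.columns = ["feature_id", "sample", "replicate", "abundance_iu"]
        meta = self.features.reset_index().rename(columns={"index": "feature_id"})
        if "feature_id" not in meta.columns:
            meta = meta.rename(columns={meta.columns[0]: "feature_id"})
        out = meta.merge(long, on="feature_id")
        return out[["feature_id", "neutral_mass_da", "rt_min", "ion_mode", "sample", "replicate", "abundance_iu"]]

    @classmethod
    def from_long(cls, long: pd.DataFrame, provenance: str = "") -> "FeatureTable":
        required = {"feature_id", *RAW_COLUMNS}
        missing = required - set(long.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        meta = (
            long[["feature_id", "neutral_mass_da", "rt_min", "ion_mode"]]
            .drop_duplicates("feature_id")
            .set_index("feature_id")
        )
        wide = long.pivot_table(
            index="feature_id", columns=["sample", "replicate"], values="abundance_iu", aggfunc="first"
        )
        if wide.isna().any().any():
            raise ValueError("every feature needs an abundance for every (sample, replicate)")
        # preserve the sample/replicate order of the long table (pivot sorts)
        samples = list(dict.fromkeys(long["sample"]))
        reps = list(dict.fromkeys(long["replicate"]))
        wide = wide.reindex(columns=pd.MultiIndex.from_product([samples, reps], names=["sample", "replicate"]))
        wide = wide.loc[meta.index]
        return cls(features=meta, abundances=wide, provenance=provenance)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_removed: int
    n_retained: int
    threshold_iu: float


@dataclass
class QCReport:
    """Shot-noise consistency of replicate measurements.

    ``measurements``: one row per (feature, sample) with mean abundance at
    or above the reporting floor, its observed and expected RSD, and a
    consistency flag.
    """

    measurements: pd.DataFrame
    consistent_fraction: float
    tolerance_factor: float
    iu_per_ion: float


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _component_labels(masses: np.ndarray, rts: np.ndarray, mass_tol_ppm: float, rt_tol_min: float) -> np.ndarray:
    """Single-linkage components under (ppm AND rt) tolerances, sorted-window scan."""
    n = len(masses)
    order = np.argsort(masses, kind="stable")
    uf = _UnionFind(n)
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            # masses sorted: once the one-sided gap exceeds the tolerance no
            # later partner can be within it (pair-mean ppm <= one-sided ppm).
            if (masses[j] - masses[i]) / masses[i] * 1e6 > mass_tol_ppm:
                break
            if ppm_difference(masses[i], masses[j]) <= mass_tol_ppm and abs(rts[i] - rts[j]) <= rt_tol_min:
                uf.union(i, j)
    roots = np.array([uf.find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def align_features(
    raw: pd.DataFrame,
    mass_tol_ppm: float = 6.0,
    rt_tol_min: float = 0.25,
    sample_names: list[str] | None = None,
    replicates: list | None = None,
    noise_gate_factor: float = 3.0,
) -> FeatureTable:
    """Merge raw per-replicate observations into an aligned feature table.

    ``raw`` is a long DataFrame with columns ``neutral_mass_da``, ``rt_min``,
    ``ion_mode``, ``sample``, ``replicate``, ``abundance_iu`` and optionally
    ``noise_iu``.  Observations in the same ion mode whose pairwise mass
    difference is within ``mass_tol_ppm`` AND retention-time difference
    within ``rt_tol_min`` are grouped by single-linkage transitive closure;
    each group becomes one feature whose abundance per (sample, replicate)
    is the sum of its members and whose mass/RT are abundance-weighted
    means.  Features matching across the two ionization modes under the
    same tolerances are de-duplicated (the higher-abundance mode's values
    are kept) and flagged ``ion_mode='both'``.

    When a ``noise_iu`` column is present, observations below
    ``noise_gate_factor`` x their noise level are dropped before grouping
    (peak-picking style gate); without the column no gate is applied.
    """
    raw = raw.copy()
    missing = set(RAW_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"raw feature table is missing columns: {sorted(missing)}")
    if "noise_iu" in raw.columns:
        raw = raw[raw["abundance_iu"] >= noise_gate_factor * raw["noise_iu"]]

    if sample_names is None:
        sample_names = list(dict.fromkeys(raw["sample"]))
    if replicates is None:
        replicates = sorted(raw["replicate"].unique()) if len(raw) else []
    columns = pd.MultiIndex.from_product([sample_names, replicates], names=["sample", "replicate"])

    if raw.empty:
        features = pd.DataFrame(columns=["neutral_mass_da", "rt_min", "ion_mode"])
        features.index.name = "feature_id"
        return FeatureTable(features=features, abundances=pd.DataFrame(index=features.index, columns=columns, dtype=float))

    merged_rows: list[dict] = []
    for mode in ("positive", "negative", "both"):
        sub = raw[raw["ion_mode"] == mode]
        if sub.empty:
            continue
        masses = sub["neutral_mass_da"].to_numpy(float)
        rts = sub["rt_min"].to_numpy(float)
        labels = _component_labels(masses, rts, mass_tol_ppm, rt_tol_min)
        for label in np.unique(labels):
            members = sub.iloc[np.flatnonzero(labels == label)]
            weights = members["abundance_iu"].to_numpy(float)
            if weights.sum() > 0:
                w = weights / weights.sum()
            else:
                w = np.full(len(members), 1.0 / len(members))
            abundance = np.zeros(len(columns))
            col_pos = {key: k for k, key in enumerate(columns)}
            for _, row in members.iterrows():
                key = (row["sample"], row["replicate"])
                if key not in col_pos:
                    raise ValueError(f"observation for unknown sample/replicate {key}")
                abundance[col_pos[key]] += row["abundance_iu"]
            merged_rows.append(
                {
                    "neutral_mass_da": float(np.dot(w, members["neutral_mass_da"].to_numpy(float))),
                    "rt_min": float(np.dot(w, members["rt_min"].to_numpy(float))),
                    "ion_mode": mode,
                    "abundance": abundance,
                }
            )

    merged_rows = _deduplicate_modes(merged_rows, mass_tol_ppm, rt_tol_min)

    width = int(math.ceil(math.log10(max(len(merged_rows), 1) + 1))) + 1
    ids = [f"F{k + 1:0{width}d}" for k in range(len(merged_rows))]
    features = pd.DataFrame(
        {
            "neutral_mass_da": [r["neutral_mass_da"] for r in merged_rows],
            "rt_min": [r["rt_min"] for r in merged_rows],
            "ion_mode": [r["ion_mode"] for r in merged_rows],
        },
        index=pd.Index(ids, name="feature_id"),
    )
    abundances = pd.DataFrame(
        np.vstack([r["abundance"] for r in merged_rows]) if merged_rows else None,
        index=features.index,
        columns=columns,
    )
    return FeatureTable(features=features, abundances=abundances, provenance="align_features")


def _deduplicate_modes(rows: list[dict], mass_tol_ppm: float, rt_tol_min: float) -> list[dict]:
    """Count features found in both ionization modes once.

    Positive/negative features matching under the alignment tolerances form
    cross-mode groups; within each group only the member with the highest
    total abundance is kept, relabeled ``both``.
    """
    pos = [k for k, r in enumerate(rows) if r["ion_mode"] == "positive"]
    neg = [k for k, r in enumerate(rows) if r["ion_mode"] == "negative"]
    if not pos or not neg:
        return rows
    uf = _UnionFind(len(rows))
    for i in pos:
        for j in neg:
            if (
                ppm_difference(rows[i]["neutral_mass_da"], rows[j]["neutral_mass_da"]) <= mass_tol_ppm
                and abs(rows[i]["rt_min"] - rows[j]["rt_min"]) <= rt_tol_min
            ):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for k in range(len(rows)):
        groups.setdefault(uf.find(k), []).append(k)
    kept: list[dict] = []
    for members in groups.values():
        modes = {rows[k]["ion_mode"] for k in members}
        if len(members) == 1 or not {"positive", "negative"} <= modes:
            kept.extend(rows[k] for k in members)
            continue
        best = max(members, key=lambda k: rows[k]["abundance"].sum())
        winner = dict(rows[best])
        winner["ion_mode"] = "both"
        kept.append(winner)
    kept.sort(key=lambda r: (r["neutral_mass_da"], r["rt_min"]))
    return kept


def filter_low_abundance(
    table: FeatureTable, threshold_iu: float = 1000.0
) -> tuple[FeatureTable, FilterReport]:
    """Drop features whose per-sample mean abundance is below the threshold
    in *every* sample; one sample at or above the threshold retains the
    feature (the cut is strict: exactly-threshold means are kept)."""
    means = table.sample_means()
    keep = (means >= threshold_iu).any(axis=1)
    report = FilterReport(
        n_input=len(table),
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        threshold_iu=threshold_iu,
    )
    return table.subset(means.index[keep]), report


def expected_shot_noise_rsd(abundance_iu: float, iu_per_ion: float = DEFAULT_IU_PER_ION) -> float:
    """RSD expected from ion-counting statistics alone: 1/sqrt(ions)."""
    if abundance_iu <= 0:
        raise ValueError("abundance must be positive")
    n_ions = abundance_iu / iu_per_ion
    return 1.0 / math.sqrt(n_ions)


def qc_shot_noise(
    table: FeatureTable,
    tolerance_factor: float = 2.0,
    min_mean_iu: float = 1000.0,
    iu_per_ion: float = DEFAULT_IU_PER_ION,
) -> QCReport:
    """Compare observed replicate RSDs with the shot-noise expectation.

    A (feature, sample) triplicate whose mean is at least ``min_mean_iu``
    is *consistent* when its observed RSD (sample sd / mean) does not
    exceed ``tolerance_factor`` times the expected shot-noise RSD at that
    mean.
    """
    if table.replicate_count < 2:
        raise ValueError("shot-noise QC needs at least two replicates")
    rows = []
    for sample in table.sample_names:
        block = table.abundances[sample]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        sel = mean >= min_mean_iu
        for fid in mean.index[sel]:
            expected = expected_shot_noise_rsd(float(mean[fid]), iu_per_ion)
            observed = float(sd[fid] / mean[fid])
            rows.append(
                {
                    "feature_id": fid,
                    "sample": sample,
                    "mean_iu": float(mean[fid]),
                    "observed_rsd": observed,
                    "expected_rsd": expected,
                    "consistent": observed <= tolerance_factor * expected,
                }
            )
    measurements = pd.DataFrame(rows, columns=["feature_id", "sample", "mean_iu", "observed_rsd", "expected_rsd", "consistent"])
    fraction = float(measurements["consistent"].mean()) if len(measurements) else float("nan")
    return QCReport(
        measurements=measurements,
        consistent_fraction=fraction,
        tolerance_factor=tolerance_factor,
        iu_per_ion=iu_per_ion,
    )


def write_feature_table(table: FeatureTable, path) -> None:
    table.to_long().to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> FeatureTable:
    long = pd.read_csv(path, sep="\t")
    return FeatureTable.from_long(long, provenance=str(path))


def read_raw_features(path) -> pd.DataFrame:
    """Read an unaligned per-replicate observation table (long TSV)."""
    raw = pd.read_csv(path, sep="\t")
    missing = set(RAW_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return raw
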