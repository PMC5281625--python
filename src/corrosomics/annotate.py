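"""Putative metabolite identification.

Features are matched against a compound library by exact neutral mass
(default 6 ppm).  For positive-ion-mode features a quantitative
structure-retention relationship (QSRR) — ordinary least squares of
retention time on six physico-chemical descriptors — predicts the expected
retention time, and candidates more than 45% off the prediction are
rejected.  Each retained candidate receives a 1-10 confidence score built
from the mass error, the retention-time deviation, and a database priority
order; the highest-confidence candidate is selected per feature.  Accepted
identifications roll up into per-pathway metabolite counts and abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chem_mass import MolecularFormula, mass_error, monoisotopic_mass, parse_formula
from .feature_pipeline import FeatureTable

__all__ = [
    "CompoundRecord",
    "RTModel",
    "Annotation",
    "DEFAULT_DB_PRIORITY",
    "fit_rt_model",
    "predict_rt",
    "match_features",
    "confidence_score",
    "select_best",
    "annotate_table",
    "map_pathways",
    "read_compound_library",
    "write_compound_library",
    "read_rt_standards",
]

N_DESCRIPTORS = 6

#: default ranked database priority (rank 1 = most trusted).
DEFAULT_DB_PRIORITY = {"KEGG": 1, "MetaCyc": 2, "HMDB": 3, "LipidMaps": 4}


@dataclass
class CompoundRecord:
    compound_id: str
    name: str
    formula: MolecularFormula
    source_db: str = "KEGG"
    db_priority: int = 1
    pathway_ids: tuple[str, ...] = ()
    descriptors: np.ndarray | None = None
    reference_rt: float | None = None

    def __post_init__(self) -> None:
        if self.db_priority < 1:
            raise ValueError("db_priority is a rank >= 1")
        if self.descriptors is not None:
            self.descriptors = np.asarray(self.descriptors, dtype=float)
            if self.descriptors.shape != (N_DESCRIPTORS,):
                raise ValueError(f"descriptors must have length {N_DESCRIPTORS}")

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class RTModel:
    """Linear retention-time model: rt = intercept + coefficients . descriptors."""

    intercept: float
    coefficients: tuple[float, ...]
    n_calibration: int
    residual_sd: float
    stderr: tuple[float, ...] = ()

    def predict(self, descriptors: Sequence[float]) -> float:
        d = np.asarray(descriptors, dtype=float)
        if d.shape != (N_DESCRIPTORS,):
            raise ValueError(f"descriptors must have length {N_DESCRIPTORS}")
        return float(self.intercept + np.dot(self.coefficients, d))


@dataclass
class Annotation:
    feature_id: str
    compound_id: str
    mass_error_ppm: float
    predicted_rt: float | None = None
    rt_deviation_fraction: float | None = None
    confidence: int = 1
    accepted: bool = False
    matched_standard: bool = False


def fit_rt_model(descriptors: np.ndarray, observed_rt: Sequence[float]) -> RTModel:
    """OLS fit of retention time on the six descriptors plus an intercept.

    Needs at least 8 calibration standards (7 parameters + 1 residual
    degree of freedom) and a full-rank descriptor matrix.
    """
    X = np.asarray(descriptors, dtype=float)
    y = np.asarray(observed_rt, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_DESCRIPTORS:
        raise ValueError(f"descriptor matrix must be (n, {N_DESCRIPTORS})")
    n = X.shape[0]
    if n < N_DESCRIPTORS + 2:
        raise ValueError(
            f"need at least {N_DESCRIPTORS + 2} calibration standards, got {n}"
        )
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < N_DESCRIPTORS + 1:
        raise ValueError("descriptor matrix is rank deficient; drop collinear descriptors")
    fit = sm.OLS(y, design).fit()
    residual_sd = float(np.sqrt(fit.scale))
    return RTModel(
        intercept=float(fit.params[0]),
        coefficients=tuple(float(b) for b in fit.params[1:]),
        n_calibration=n,
        residual_sd=residual_sd,
        stderr=tuple(float(s) for s in fit.bse[1:]),
    )


def predict_rt(model: RTModel, compound: CompoundRecord) -> float | None:
    """Predicted retention time, or None when the compound has no descriptors."""
    if compound.descriptors is None:
        return None
    return model.predict(compound.descriptors)


def confidence_score(
    mass_error_ppm: float,
    rt_deviation_fraction: float | None,
    db_priority: int,
    mass_tol_ppm: float = 6.0,
    rt_reject_fraction: float = 0.45,
    matched_standard: bool = False,
) -> int:
    """Deterministic 1-10 confidence rubric.

    Starts at 10 and subtracts three linear penalties:

    * mass error: 0-3, linear in ``|ppm| / mass_tol_ppm``;
    * retention time: 0-3, linear in ``deviation / rt_reject_fraction``;
      a flat 1 when no prediction is available;
    * database priority: rank 1 -> 0 ... rank >= 4 -> 3.

    The raw score is rounded half-up and clamped to [1, 10].  A match to an
    authentic standard (reference RT within 10%) forces 10.
    """
    if matched_standard:
        return 10
    penalty = 3.0 * min(abs(mass_error_ppm) / mass_tol_ppm, 1.0)
    if rt_deviation_fraction is None:
        penalty += 1.0
    else:
        penalty += 3.0 * min(rt_deviation_fraction / rt_reject_fraction, 1.0)
    penalty += float(min(db_priority, 4) - 1)
    score = math.floor(10.0 - penalty + 0.5)  # round half-up
    return int(min(10, max(1, score)))


def match_features(
    table: FeatureTable,
    library: Sequence[CompoundRecord],
    mass_tol_ppm: float = 6.0,
    rt_model: RTModel | None = None,
    rt_reject_fraction: float = 0.45,
    standard_rt_fraction: float = 0.10,
) -> dict[str, list[Annotation]]:
    """All library candidates per feature under the mass (and RT) gates.

    The RT gate applies only to features observed in positive ion mode
    (including dual-mode features), where the HILIC separation makes the
    QSRR prediction meaningful; negative-mode features are matched on mass
    alone.  Candidates whose relative RT deviation exceeds
    ``rt_reject_fraction`` are rejected.  A candidate with a reference RT
    within ``standard_rt_fraction`` of the observed RT counts as matched to
    an authentic standard.
    """
    if not library:
        raise ValueError("compound library is empty")
    lib_masses = np.array([c.monoisotopic_mass for c in library])
    order = np.argsort(lib_masses)
    sorted_masses = lib_masses[order]

    out: dict[str, list[Annotation]] = {}
    for fid, row in table.features.iterrows():
        mass = float(row["neutral_mass_da"])
        rt = float(row["rt_min"])
        gate_rt = row["ion_mode"] in ("positive", "both")
        lo = np.searchsorted(sorted_masses, mass * (1 - 1.5e-6 * mass_tol_ppm))
        hi = np.searchsorted(sorted_masses, mass * (1 + 1.5e-6 * mass_tol_ppm))
        candidates: list[Annotation] = []
        for k in order[lo:hi]:
            compound = library[k]
            err = mass_error(mass, lib_masses[k]).ppm
            if abs(err) > mass_tol_ppm:
                continue
            predicted = predict_rt(rt_model, compound) if rt_model is not None else None
            deviation = None
            if gate_rt and predicted is not None and predicted > 0:
                deviation = abs(rt - predicted) / predicted
                if deviation > rt_reject_fraction:
                    continue
            matched_standard = (
                compound.reference_rt is not None
                and compound.reference_rt > 0
                and abs(rt - compound.reference_rt) / compound.reference_rt <= standard_rt_fraction
            )
            candidates.append(
                Annotation(
                    feature_id=str(fid),
                    compound_id=compound.compound_id,
                    mass_error_ppm=float(err),
                    predicted_rt=predicted,
                    rt_deviation_fraction=deviation,
                    confidence=confidence_score(
                        err,
                        deviation if gate_rt else None,
                        compound.db_priority,
                        mass_tol_ppm=mass_tol_ppm,
                        rt_reject_fraction=rt_reject_fraction,
                        matched_standard=matched_standard,
                    ),
                    accepted=True,
                    matched_standard=matched_standard,
                )
            )
        if candidates:
            out[str(fid)] = candidates
    return out


def select_best(
    candidates: Sequence[Annotation], library_by_id: dict[str, CompoundRecord] | None = None
) -> Annotation | None:
    """Highest confidence wins; deterministic tie-break by (database rank,
    |mass error|, compound id)."""
    if not candidates:
        return None

    def priority(a: Annotation) -> int:
        if library_by_id is None:
            return 1
        return library_by_id[a.compound_id].db_priority

    return min(
        candidates,
        key=lambda a: (-a.confidence, priority(a), abs(a.mass_error_ppm), a.compound_id),
    )


def annotate_table(
    table: FeatureTable,
    library: Sequence[CompoundRecord],
    rt_model: RTModel | None = None,
    mass_tol_ppm: float = 6.0,
    rt_reject_fraction: float = 0.45,
) -> dict[str, Annotation]:
    """Best accepted annotation per feature (features with no match absent)."""
    by_id = {c.compound_id: c for c in library}
    matches = match_features(
        table, library, mass_tol_ppm=mass_tol_ppm, rt_model=rt_model, rt_reject_fraction=rt_reject_fraction
    )
    return {fid: select_best(cands, by_id) for fid, cands in matches.items()}


def map_pathways(
    annotations: dict[str, Annotation],
    library: Sequence[CompoundRecord],
    table: FeatureTable | None = None,
) -> pd.DataFrame:
    """Roll accepted annotations up to pathways.

    Returns a DataFrame indexed by pathway id with ``n_metabolites`` and
    ``total_abundance_iu`` (summed per-sample mean abundance over all
    samples; zero when no table is supplied).  Compounds without any
    pathway membership accumulate under ``unassigned``.
    """
    by_id = {c.compound_id: c for c in library}
    means = table.sample_means().sum(axis=1) if table is not None else None
    counts: dict[str, int] = {}
    abundance: dict[str, float] = {}
    for fid, ann in annotations.items():
        if ann is None or not ann.accepted:
            continue
        compound = by_id[ann.compound_id]
        pathways = compound.pathway_ids or ("unassigned",)
        contrib = float(means.get(fid, 0.0)) if means is not None else 0.0
        for p in pathways:
            counts[p] = counts.get(p, 0) + 1
            abundance[p] = abundance.get(p, 0.0) + contrib
    out = pd.DataFrame(
        {
            "n_metabolites": pd.Series(counts, dtype=int),
            "total_abundance_iu": pd.Series(abundance, dtype=float),
        }
    )
    out.index.name = "pathway_id"
    return out.sort_index()


# ---------------------------------------------------------------------------
# delimited-text interfaces

_LIBRARY_COLUMNS = [
    "compound_id", "name", "formula", "source_db", "db_priority", "pathway_ids",
    "d1", "d2", "d3", "d4", "d5", "d6", "reference_rt",
]


def write_compound_library(library: Sequence[CompoundRecord], path) -> None:
    rows = []
    for c in library:
        row = {
            "compound_id": c.compound_id,
            "name": c.name,
            "formula": str(c.formula),
            "source_db": c.source_db,
            "db_priority": c.db_priority,
            "pathway_ids": ";".join(c.pathway_ids),
            "reference_rt": "" if c.reference_rt is None else c.reference_rt,
        }
        for k in range(N_DESCRIPTORS):
            row[f"d{k + 1}"] = "" if c.descriptors is None else c.descriptors[k]
        rows.append(row)
    pd.DataFrame(rows, columns=_LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_compound_library(path) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"pathway_ids": str})
    missing = set(_LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        d = row[[f"d{k + 1}" for k in range(N_DESCRIPTORS)]].to_numpy(dtype=float)
        descriptors = None if np.isnan(d).any() else d
        pathways = row["pathway_ids"]
        pathway_ids = tuple(p for p in str(pathways).split(";") if p) if pd.notna(pathways) else ()
        rt = row["reference_rt"]
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                name=str(row["name"]),
                formula=parse_formula(str(row["formula"])),
                source_db=str(row["source_db"]),
                db_priority=int(row["db_priority"]),
                pathway_ids=pathway_ids,
                descriptors=descriptors,
                reference_rt=None if pd.isna(rt) else float(rt),
            )
        )
    return records


def read_rt_standards(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a calibration-standards table: d1..d6 and observed_rt_min."""
    df = pd.read_csv(path, sep="\t")
    cols = [f"d{k + 1}" for k in range(N_DESCRIPTORS)]
    missing = set(cols + ["observed_rt_min"]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[cols].to_numpy(dtype=float), df["observed_rt_min"].to_numpy(dtype=float)
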