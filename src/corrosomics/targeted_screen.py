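"""Targeted screening for hydrocarbon-degradation metabolites.

Anaerobic activation of alkanes and alkylated aromatics proceeds by
addition across the double bond of fumarate, yielding homologous series of
alkylsuccinates (C(n+4)H(2n+6)O4 for an n-carbon alkyl chain) and
benzylsuccinates (C(11+m)H(12+2m)O4 for m methyl/alkyl carbons on the
ring/chain).  These metabolites are diagnostic: finding the series in a
metabolome implicates fumarate-addition metabolism even when the
responsible genes escape detection.  Aerobic counterparts (hydroxylated
aromatics such as methylbenzylalcohol) are screened as single targets.

Positive identification is deliberately stricter than untargeted
annotation: the mass must match within +/-2 ppm and, when a retention time
can be anchored to an authentic standard or interpolated along the series,
the observed RT must be within +/-10% of the expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem_mass import MolecularFormula, mass_error, monoisotopic_mass, parse_formula
from .feature_pipeline import FeatureTable

__all__ = [
    "HomologSeries",
    "SingleTarget",
    "Detection",
    "alkylsuccinate_formula",
    "benzylsuccinate_formula",
    "make_series",
    "expected_rt",
    "screen",
    "reference_targets",
    "read_targets",
    "write_targets",
]


def alkylsuccinate_formula(n: int) -> MolecularFormula:
    """Succinate bearing an n-carbon alkyl chain: C(n+4)H(2n+6)O4.

    n=2 is ethylsuccinic acid (C6H10O4), n=6 hexylsuccinic acid (C10H18O4).
    """
    if n < 1:
        raise ValueError("alkyl chain needs at least one carbon")
    return MolecularFormula({"C": n + 4, "H": 2 * n + 6, "O": 4})


def benzylsuccinate_formula(m: int) -> MolecularFormula:
    """Benzylsuccinate with m extra methyl/alkyl carbons: C(11+m)H(12+2m)O4.

    m=0 is benzylsuccinic acid itself, m=1 the methyl benzylsuccinate /
    phenylethylsuccinate isomers (C12H14O4).
    """
    if m < 0:
        raise ValueError("m counts additional carbons and cannot be negative")
    return MolecularFormula({"C": 11 + m, "H": 12 + 2 * m, "O": 4})


_FAMILIES: dict[str, Callable[[int], MolecularFormula]] = {
    "alkylsuccinate": alkylsuccinate_formula,
    "benzylsuccinate": benzylsuccinate_formula,
}


@dataclass
class HomologSeries:
    """A carbon-number-indexed family of target formulas with RT anchors."""

    series_name: str
    formula_rule: Callable[[int], MolecularFormula]
    n_range: tuple[int, int]
    #: (carbon number, retention time in minutes) from authentic standards
    #: or culture extracts; >=2 anchors enable interpolation along n.
    anchor_rts: list[tuple[int, float]] = field(default_factory=list)

    def members(self) -> list[tuple[int, MolecularFormula, float]]:
        lo, hi = self.n_range
        out = []
        for n in range(lo, hi + 1):
            f = self.formula_rule(n)
            out.append((n, f, monoisotopic_mass(f)))
        return out


@dataclass
class SingleTarget:
    """A one-off screening target with an optional per-compound reference RT."""

    name: str
    formula: MolecularFormula
    reference_rt: float | None = None


@dataclass(frozen=True)
class Detection:
    series_name: str
    n: int | None
    feature_id: str
    theoretical_mass_da: float
    mass_error_ppm: float
    rt_deviation_fraction: float | None
    rt_extrapolated: bool
    mass_only: bool
    most_abundant: bool
    total_abundance_iu: float


def make_series(
    family: str,
    n_range: tuple[int, int],
    anchor_rts: Sequence[tuple[int, float]] = (),
    series_name: str | None = None,
) -> HomologSeries:
    if family not in _FAMILIES:
        raise ValueError(f"unknown homolog family {family!r}; known: {sorted(_FAMILIES)}")
    return HomologSeries(
        series_name=series_name or family,
        formula_rule=_FAMILIES[family],
        n_range=tuple(n_range),
        anchor_rts=sorted(anchor_rts),
    )


def expected_rt(series: HomologSeries, n: int) -> tuple[float | None, bool]:
    """Expected retention time for member n, with an extrapolation flag.

    Piecewise-linear interpolation of RT against carbon number through the
    anchors; outside the anchored range the terminal segment is extended
    linearly and flagged.  With a single anchor only that member is gated;
    with none, the screen falls back to mass-only.
    """
    anchors = sorted(series.anchor_rts)
    if not anchors:
        return None, False
    ns = np.array([a[0] for a in anchors], dtype=float)
    rts = np.array([a[1] for a in anchors], dtype=float)
    if len(anchors) == 1:
        return (float(rts[0]), False) if n == int(ns[0]) else (None, False)
    if n < ns[0]:
        slope = (rts[1] - rts[0]) / (ns[1] - ns[0])
        return float(rts[0] + slope * (n - ns[0])), True
    if n > ns[-1]:
        slope = (rts[-1] - rts[-2]) / (ns[-1] - ns[-2])
        return float(rts[-1] + slope * (n - ns[-1])), True
    return float(np.interp(n, ns, rts)), False


def screen(
    table: FeatureTable,
    series: Sequence[HomologSeries] = (),
    singles: Sequence[SingleTarget] = (),
    mass_tol_ppm: float = 2.0,
    rt_tol_fraction: float = 0.10,
) -> list[Detection]:
    """Screen an aligned feature table against homolog series and single targets.

    A feature qualifies for a (series, n) member iff its mass error against
    the theoretical mass is within ``mass_tol_ppm`` AND, when an expected
    RT exists, its relative RT deviation is within ``rt_tol_fraction``.
    All qualifying features are reported (co-eluting isomers co-qualify);
    the most abundant per target is flagged.
    """
    masses = table.features["neutral_mass_da"].to_numpy(float)
    rts = table.features["rt_min"].to_numpy(float)
    totals = table.sample_means().sum(axis=1).to_numpy(float)
    fids = table.features.index.to_numpy()

    detections: list[Detection] = []

    def check_target(name: str, n: int | None, theo: float, rt_expect: float | None, extrapolated: bool) -> None:
        hits = []
        for k in range(len(fids)):
            err = mass_error(masses[k], theo).ppm
            if abs(err) > mass_tol_ppm:
                continue
            deviation = None
            if rt_expect is not None and rt_expect > 0:
                deviation = abs(rts[k] - rt_expect) / rt_expect
                if deviation > rt_tol_fraction:
                    continue
            hits.append((k, err, deviation))
        if not hits:
            return
        best = max(hits, key=lambda h: totals[h[0]])[0]
        for k, err, deviation in hits:
            detections.append(
                Detection(
                    series_name=name,
                    n=n,
                    feature_id=str(fids[k]),
                    theoretical_mass_da=theo,
                    mass_error_ppm=float(err),
                    rt_deviation_fraction=deviation,
                    rt_extrapolated=extrapolated,
                    mass_only=rt_expect is None,
                    most_abundant=k == best,
                    total_abundance_iu=float(totals[k]),
                )
            )

    for s in series:
        for n, _formula, theo in s.members():
            rt_expect, extrapolated = expected_rt(s, n)
            check_target(s.series_name, n, theo, rt_expect, extrapolated)
    for t in singles:
        check_target(t.name, None, monoisotopic_mass(t.formula), t.reference_rt, False)
    return detections


def reference_targets(
    n_range_alkyl: tuple[int, int] = (1, 12),
    m_range_benzyl: tuple[int, int] = (0, 6),
) -> tuple[list[HomologSeries], list[SingleTarget]]:
    """Default screen targets built from the packaged diagnostic-metabolite
    table: the alkylsuccinate series anchored at the authentic-standard
    retention times, the benzylsuccinate series anchored at its one
    standard, and the aerobic hydroxylated aromatics as single targets."""
    from importlib import resources

    df = pd.read_csv(
        resources.files("corrosomics.data").joinpath("diagnostic_metabolites.tsv"), sep="\t"
    )
    alkyl_anchors = []
    benzyl_anchors = []
    singles: list[SingleTarget] = []
    for _, row in df.iterrows():
        series = row["series"] if isinstance(row["series"], str) else ""
        if series == "alkylsuccinate":
            alkyl_anchors.append((int(row["n"]), float(row["reference_rt_min"])))
        elif series == "benzylsuccinate":
            benzyl_anchors.append((int(row["n"]), float(row["reference_rt_min"])))
        else:
            singles.append(
                SingleTarget(
                    name=str(row["name"]),
                    formula=parse_formula(str(row["formula"])),
                    reference_rt=float(row["reference_rt_min"]),
                )
            )
    series_list = [
        make_series("alkylsuccinate", n_range_alkyl, alkyl_anchors),
        make_series("benzylsuccinate", m_range_benzyl, benzyl_anchors),
    ]
    return series_list, singles


# ---------------------------------------------------------------------------
# delimited-text target definitions

_TARGET_COLUMNS = ["target_type", "name", "family", "formula", "n_min", "n_max", "n", "anchor_rt_min"]


def write_targets(path, series: Sequence[HomologSeries] = (), singles: Sequence[SingleTarget] = ()) -> None:
    rows = []
    for s in series:
        family = next((k for k, v in _FAMILIES.items() if v is s.formula_rule), "")
        rows.append(
            {"target_type": "series", "name": s.series_name, "family": family,
             "formula": "", "n_min": s.n_range[0], "n_max": s.n_range[1], "n": "", "anchor_rt_min": ""}
        )
        for n, rt in s.anchor_rts:
            rows.append(
                {"target_type": "anchor", "name": s.series_name, "family": family,
                 "formula": "", "n_min": "", "n_max": "", "n": n, "anchor_rt_min": rt}
            )
    for t in singles:
        rows.append(
            {"target_type": "compound", "name": t.name, "family": "", "formula": str(t.formula),
             "n_min": "", "n_max": "", "n": "", "anchor_rt_min": "" if t.reference_rt is None else t.reference_rt}
        )
    pd.DataFrame(rows, columns=_TARGET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_targets(path) -> tuple[list[HomologSeries], list[SingleTarget]]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TARGET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    series: dict[str, HomologSeries] = {}
    singles: list[SingleTarget] = []
    for _, row in df.iterrows():
        kind = row["target_type"]
        if kind == "series":
            series[row["name"]] = make_series(
                row["family"], (int(row["n_min"]), int(row["n_max"])), series_name=row["name"]
            )
        elif kind == "anchor":
            if row["name"] not in series:
                raise ValueError(f"anchor row for unknown series {row['name']!r}")
            series[row["name"]].anchor_rts.append((int(row["n"]), float(row["anchor_rt_min"])))
        elif kind == "compound":
            rt = row["anchor_rt_min"]
            singles.append(
                SingleTarget(
                    name=str(row["name"]),
                    formula=parse_formula(str(row["formula"])),
                    reference_rt=None if pd.isna(rt) else float(rt),
                )
            )
        else:
            raise ValueError(f"unknown target_type {kind!r}")
    for s in series.values():
        s.anchor_rts.sort()
    return list(series.values()), singles
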