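"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design this package analyzes: four pigging
samples (LC3, LC11, HC3, HC11) from a low- and a high-corrosion pipeline,
each profiled in triplicate by LC-MS in two ionization modes, plus genome
bins and gene counts from four shotgun metagenomes.  Every table comes with
recorded ground truth so downstream statistics can be checked against the
values the generator put in.

Model of the metabolome:

* library metabolites are random valence-consistent CHNOPS formulas (the
  hydrogen count is derived from a sampled degree of unsaturation, so the
  nitrogen rule holds exactly);
* per-sample true abundances are log-normal with a system-level enrichment
  effect for a configurable fraction of compounds; per-sample odd-mass
  abundance shares are then calibrated to configurable RN targets;
* replicate abundances add Poisson ion-counting shot noise at
  ``iu_per_ion`` instrument units per ion;
* "exochemical" background features carry masses rejection-sampled to
  match no library entry within the annotation tolerance, emulating the
  non-identifiable fraction of a real pipeline metabolome;
* optional spike-ins place an alkylsuccinate homolog series at authentic
  retention-time anchors.

Metagenome tables invert the coverage estimator: a bin occupying community
fraction p in a sample gets coverage p * total_bases / length (times
multiplicative noise), so the coverage-based cell-fraction estimate should
recover p.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import DEFAULT_DB_PRIORITY, CompoundRecord, RTModel, write_compound_library
from .chem_mass import MolecularFormula, formula_nitrogen_parity, monoisotopic_mass, nitrogen_parity
from .feature_pipeline import DEFAULT_IU_PER_ION, FeatureTable, write_feature_table
from .metagenome_tea import (
    DEFAULT_PATHWAYS,
    GenomeBin,
    PathwayDefinition,
    call_pathway,
    write_bin_table,
    write_pathway_definitions,
)
from .metabolome_stats import DEFAULT_SYSTEM_MAP
from .targeted_screen import alkylsuccinate_formula, benzylsuccinate_formula

__all__ = [
    "GeneratorConfig",
    "BinSpec",
    "SpikeSpec",
    "GroundTruth",
    "MetagenomeTruth",
    "SimulationBundle",
    "default_spikes",
    "default_bins",
    "default_metagenome_sizes",
    "generate_library",
    "generate_rt_standards",
    "generate_feature_tables",
    "generate_metagenome_tables",
    "simulate_metabolome",
    "simulate_metagenome",
    "write_all",
]

SAMPLES = ("LC3", "LC11", "HC3", "HC11")


@dataclass(frozen=True)
class SpikeSpec:
    """A targeted-screen spike-in: one homolog-series member at an anchor RT."""

    family: str  # alkylsuccinate | benzylsuccinate
    n: int
    rt_min: float
    abundances: tuple[tuple[str, float], ...]  # (sample, mean i.u.)


@dataclass(frozen=True)
class BinSpec:
    """Ground-truth description of one genome bin in the synthetic community."""

    bin_id: str
    site: str
    total_length: int
    fractions: tuple[tuple[str, float], ...]  # (sample, community fraction)
    genes: tuple[str, ...]
    recruitment_label: str = ""
    contig_count: int = 50


def default_metagenome_sizes() -> dict[str, tuple[int, int]]:
    """sample -> (total_reads, total_bases) for the four pipeline metagenomes."""
    text = resources.files("corrosomics.data").joinpath("metagenome_sizes.tsv").read_text()
    out = {}
    for line in text.strip().splitlines()[1:]:
        sample, reads, bases = line.split("\t")
        out[sample] = (int(reads), int(bases))
    return out


def default_spikes(scale: float = 1.0, baseline_iu: float = 1200.0) -> tuple[SpikeSpec, ...]:
    """Alkylsuccinate spike-ins at the authentic-standard retention anchors.

    Abundance profiles put the series predominantly in the late
    high-corrosion sample at the measured diagnostic abundances (times
    ``scale``), with a detectable low level everywhere else.
    """
    df = pd.read_csv(resources.files("corrosomics.data").joinpath("diagnostic_metabolites.tsv"), sep="\t")
    spikes = []
    for _, row in df.iterrows():
        if not isinstance(row["series"], str) or row["series"] != "alkylsuccinate":
            continue
        high = row["high_abundance_sample"]
        abundances = tuple(
            (s, float(row["abundance_iu"]) * scale if s == high else baseline_iu) for s in SAMPLES
        )
        spikes.append(
            SpikeSpec(
                family="alkylsuccinate",
                n=int(row["n"]),
                rt_min=float(row["reference_rt_min"]),
                abundances=abundances,
            )
        )
    return tuple(spikes)


def default_bins() -> tuple[BinSpec, ...]:
    """A two-community bin layout mirroring the pipeline survey structure:
    denitrifying pseudomonads dominate the low-corrosion samples, sulfate
    reducers and fermenters the high-corrosion ones.  Fractions are chosen
    so the pathway-positive cell fractions are 78/39% (denitrification,
    LC3/LC11) and 29/34% (sulfate reduction, HC3/HC11), with a 1.5/1.6%
    sulfate-reducing minority in the LC community."""
    z = (("LC3", 0.0), ("LC11", 0.0), ("HC3", 0.0), ("HC11", 0.0))

    def fr(**kw: float) -> tuple[tuple[str, float], ...]:
        d = dict(z)
        d.update(kw)
        return tuple(d.items())

    denit_a = ("narG", "nirS", "norB", "nosZ", "alkB")
    denit_b = ("napA", "nirK", "norB", "nosZ", "xylM")
    srb = ("dsrA", "dsrB")
    return (
        BinSpec("LC_bin01", "LC", 4_749_114, fr(LC3=0.50, LC11=0.09), denit_a, "Pseudomonas stutzeri", 123),
        BinSpec("LC_bin02", "LC", 4_853_824, fr(LC3=0.28, LC11=0.30), denit_b, "Pseudomonas stutzeri", 43),
        BinSpec("LC_bin03", "LC", 2_136_066, fr(LC3=0.015, LC11=0.016), srb, "Desulfonatronospira thiodismutans", 116),
        BinSpec("LC_bin04", "LC", 3_244_921, fr(LC3=0.12, LC11=0.20), ("soxA",), "Methylophaga thiooxidans", 21),
        BinSpec("HC_bin01", "HC", 2_132_562, fr(HC3=0.20, HC11=0.22), srb, "Desulfonatronospira thiodismutans", 51),
        BinSpec("HC_bin02", "HC", 2_640_115, fr(HC3=0.09, HC11=0.12), srb, "Desulfohalobium retbaense", 36),
        BinSpec("HC_bin03", "HC", 2_131_658, fr(HC3=0.15, HC11=0.10), (), "Thermococcus kodakarensis", 40),
        BinSpec("HC_bin04", "HC", 1_256_481, fr(HC3=0.03, HC11=0.08), ("mcrA",), "Methanothermococcus okinawensis", 21),
        BinSpec("HC_bin05", "HC", 2_335_091, fr(HC3=0.10, HC11=0.05), (), "Thermoanaerobacter pseudethanolicus", 84),
    )


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with the study conditions as defaults."""

    seed: int = 0
    samples: tuple[str, ...] = SAMPLES
    system_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SYSTEM_MAP))
    replicates: int = 3

    # library / metabolome
    n_true_metabolites: int = 600
    n_exochemicals: int = 400
    nitrogen_probs: dict[int, float] = field(default_factory=lambda: {0: 0.35, 1: 0.35, 2: 0.15, 3: 0.15})
    log10_mean_abundance: float = 3.5
    log10_sd_abundance: float = 0.6
    frac_hc_enriched: float = 0.07
    frac_lc_enriched: float = 0.04
    log10_enrichment_effect: float = 1.2
    pig_run_log10_sd: float = 0.15
    rn_targets: dict[str, float] | None = field(
        default_factory=lambda: {"LC3": 40.0, "LC11": 55.0, "HC3": 40.0, "HC11": 30.0}
    )
    iu_per_ion: float = DEFAULT_IU_PER_ION
    shot_noise: bool = True
    mass_ppm_jitter: float = 2.0
    min_library_separation_ppm: float = 25.0
    exochemical_clearance_ppm: float = 10.0
    exochemical_mass_range: tuple[float, float] = (80.0, 480.0)
    exochemical_rt_range: tuple[float, float] = (0.5, 35.0)
    positive_mode_fraction: float = 0.72
    spikes: tuple[SpikeSpec, ...] = field(default_factory=default_spikes)

    # retention-time model truth
    rt_intercept: float = 14.0
    rt_coefficients: tuple[float, ...] = (1.2, -0.8, 0.5, 2.0, -1.5, 0.9)
    rt_noise_sd: float = 0.5
    rt_range: tuple[float, float] = (6.0, 35.0)
    feature_rt_sd: float = 0.1
    n_rt_standards: int = 33
    n_reference_standards: int = 8

    # annotation metadata
    db_probs: dict[str, float] = field(
        default_factory=lambda: {"KEGG": 0.4, "MetaCyc": 0.25, "HMDB": 0.2, "LipidMaps": 0.15}
    )
    pathway_pool: tuple[str, ...] = (
        "glycolysis", "tca_cycle", "fatty_acid_biosynthesis", "amino_acid_metabolism",
        "purine_metabolism", "porphyrin_metabolism", "taurine_metabolism", "isoprenoid_biosynthesis",
    )
    fraction_no_pathway: float = 0.3

    # metagenome community
    bins: tuple[BinSpec, ...] = field(default_factory=default_bins)
    coverage_noise_sd: float = 0.02
    mean_read_length: int = 250
    gene_length_bp: int = 1000
    metagenome_sizes: dict[str, tuple[int, int]] = field(default_factory=default_metagenome_sizes)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class LibraryTruth:
    true_rt: dict[str, float]           # compound_id -> model retention time
    rt_model: RTModel                   # the generating linear model


@dataclass
class GroundTruth:
    """What the metabolome generator actually put into the tables."""

    per_feature: pd.DataFrame           # kind, compound_id, odd parity, true per-sample means
    true_rn: dict[str, float]           # sample -> RN percent over all features
    true_rn_identified: dict[str, float]
    hc_enriched_ids: frozenset[str]
    lc_enriched_ids: frozenset[str]
    spike_features: dict[str, tuple[str, int]]


@dataclass
class MetagenomeTruth:
    cell_fraction_percent: dict[tuple[str, str], float]  # (pathway, sample) -> percent
    bin_fractions: pd.DataFrame                          # bin x sample community fraction


@dataclass
class SimulationBundle:
    config: GeneratorConfig
    library: list[CompoundRecord]
    library_truth: LibraryTruth
    standards: tuple[np.ndarray, np.ndarray]
    table: FeatureTable
    truth: GroundTruth


def _sample_formula(rng: np.random.Generator, nitrogen_probs: dict[int, float]) -> MolecularFormula:
    """A random valence-consistent CHNOPS formula with mass in [80, 500] Da."""
    n_values = np.array(sorted(nitrogen_probs))
    n_probs = np.array([nitrogen_probs[k] for k in n_values], dtype=float)
    n_probs = n_probs / n_probs.sum()
    for _ in range(1000):
        c = int(rng.integers(4, 21))
        n = int(rng.choice(n_values, p=n_probs))
        o = int(rng.integers(1, 9))
        s = int(rng.choice([0, 1], p=[0.92, 0.08]))
        p = int(rng.choice([0, 1], p=[0.96, 0.04]))
        dbe = int(rng.integers(0, c // 2 + 1))
        h = 2 * c + 2 + n + p - 2 * dbe
        if h < 1:
            continue
        counts = {"C": c, "H": h, "N": n, "O": o}
        if s:
            counts["S"] = s
        if p:
            counts["P"] = p
        formula = MolecularFormula({k: v for k, v in counts.items() if v > 0})
        if 80.0 <= monoisotopic_mass(formula) <= 500.0:
            return formula
    raise RuntimeError("could not sample a formula; constraints too tight")


def _descriptors_with_rt(config: GeneratorConfig, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    beta = np.asarray(config.rt_coefficients, dtype=float)
    lo, hi = config.rt_range
    for _ in range(1000):
        d = rng.normal(0.0, 1.0, size=beta.shape)
        rt = float(config.rt_intercept + beta @ d)
        if lo <= rt <= hi:
            return d, rt
    raise RuntimeError("could not sample descriptors in the retention-time window")


def generate_library(config: GeneratorConfig, rng: np.random.Generator | None = None) -> tuple[list[CompoundRecord], LibraryTruth]:
    """A compound library with formulas, descriptors, databases, and pathways.

    Library masses keep a minimum mutual separation (and stay clear of the
    spike-in series masses) so exact-mass matches are unambiguous at the
    annotation tolerance.
    """
    rng = config.rng() if rng is None else rng
    from .targeted_screen import reference_targets

    reserved = [
        monoisotopic_mass(alkylsuccinate_formula(s.n) if s.family == "alkylsuccinate" else benzylsuccinate_formula(s.n))
        for s in config.spikes
    ]
    ref_series, ref_singles = reference_targets()
    for srs in ref_series:
        reserved.extend(theo for _n, _f, theo in srs.members())
    reserved.extend(monoisotopic_mass(t.formula) for t in ref_singles)
    masses: list[float] = list(reserved)
    records: list[CompoundRecord] = []
    true_rt: dict[str, float] = {}
    db_names = list(config.db_probs)
    db_p = np.array([config.db_probs[k] for k in db_names], dtype=float)
    db_p /= db_p.sum()
    attempts = 0
    while len(records) < config.n_true_metabolites:
        attempts += 1
        if attempts > 200 * max(config.n_true_metabolites, 1):
            raise RuntimeError("library generation stalled; loosen the separation constraint")
        formula = _sample_formula(rng, config.nitrogen_probs)
        mass = monoisotopic_mass(formula)
        if any(abs(mass - m) / mass * 1e6 < config.min_library_separation_ppm for m in masses):
            continue
        d, rt = _descriptors_with_rt(config, rng)
        cid = f"CPD{len(records) + 1:05d}"
        db = str(rng.choice(db_names, p=db_p))
        if rng.random() < config.fraction_no_pathway or not config.pathway_pool:
            pathways: tuple[str, ...] = ()
        else:
            k = int(rng.integers(1, 3))
            pathways = tuple(sorted(rng.choice(config.pathway_pool, size=min(k, len(config.pathway_pool)), replace=False)))
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=f"synthetic metabolite {len(records) + 1}",
                formula=formula,
                source_db=db,
                db_priority=DEFAULT_DB_PRIORITY.get(db, 4),
                pathway_ids=pathways,
                descriptors=d,
                reference_rt=None,
            )
        )
        true_rt[cid] = rt
        masses.append(mass)
    # a small subset doubles as authentic standards with a reference RT
    if config.n_reference_standards and records:
        chosen = rng.choice(len(records), size=min(config.n_reference_standards, len(records)), replace=False)
        for k in chosen:
            records[k].reference_rt = true_rt[records[k].compound_id]
    model = RTModel(
        intercept=config.rt_intercept,
        coefficients=tuple(config.rt_coefficients),
        n_calibration=0,
        residual_sd=config.rt_noise_sd,
    )
    return records, LibraryTruth(true_rt=true_rt, rt_model=model)


def generate_rt_standards(config: GeneratorConfig, rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Calibration standards: descriptor matrix and noisy observed RTs."""
    rng = config.rng() if rng is None else rng
    X = np.empty((config.n_rt_standards, len(config.rt_coefficients)))
    y = np.empty(config.n_rt_standards)
    for i in range(config.n_rt_standards):
        d, rt = _descriptors_with_rt(config, rng)
        X[i] = d
        y[i] = rt + rng.normal(0.0, config.rt_noise_sd)
    return X, y


def _spike_formula(spec: SpikeSpec) -> MolecularFormula:
    if spec.family == "alkylsuccinate":
        return alkylsuccinate_formula(spec.n)
    if spec.family == "benzylsuccinate":
        return benzylsuccinate_formula(spec.n)
    raise ValueError(f"unknown spike family {spec.family!r}")


def generate_feature_tables(
    config: GeneratorConfig,
    library: list[CompoundRecord],
    library_truth: LibraryTruth,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureTable, GroundTruth]:
    """The aligned triplicate feature table plus its ground truth."""
    rng = config.rng() if rng is None else rng
    samples = list(config.samples)
    systems = config.system_map

    rows: list[dict] = []  # one per feature: mass, rt, mode, kind, compound_id, odd, true means
    lib_masses = np.array([c.monoisotopic_mass for c in library]) if library else np.empty(0)

    # --- library metabolites
    for compound in library:
        base = rng.normal(config.log10_mean_abundance, config.log10_sd_abundance)
        u = rng.random()
        if u < config.frac_hc_enriched:
            effect = {"HC": config.log10_enrichment_effect, "LC": 0.0}
        elif u < config.frac_hc_enriched + config.frac_lc_enriched:
            effect = {"HC": 0.0, "LC": config.log10_enrichment_effect}
        else:
            effect = {"HC": 0.0, "LC": 0.0}
        means = {
            s: 10.0 ** (base + effect[systems[s]] + rng.normal(0.0, config.pig_run_log10_sd))
            for s in samples
        }
        mass = compound.monoisotopic_mass * (1.0 + rng.uniform(-1, 1) * config.mass_ppm_jitter * 1e-6)
        rt = library_truth.true_rt[compound.compound_id] + rng.normal(0.0, config.feature_rt_sd)
        mode = "positive" if rng.random() < config.positive_mode_fraction else "negative"
        rows.append(
            {
                "kind": "metabolite",
                "compound_id": compound.compound_id,
                "neutral_mass_da": mass,
                "rt_min": max(rt, 0.1),
                "ion_mode": mode,
                "odd_parity": formula_nitrogen_parity(compound.formula),
                "means": means,
            }
        )

    # --- exochemical background: masses matching nothing in the library and
    # nothing on the targeted-screen lists (no decoys by construction)
    from .targeted_screen import reference_targets

    target_masses: list[float] = [monoisotopic_mass(_spike_formula(s)) for s in config.spikes]
    for s_series, s_singles in [reference_targets()]:
        for srs in s_series:
            target_masses.extend(theo for _n, _f, theo in srs.members())
        target_masses.extend(monoisotopic_mass(t.formula) for t in s_singles)
    known = (
        np.sort(np.concatenate([lib_masses, np.asarray(target_masses, dtype=float)]))
        if (len(lib_masses) or target_masses)
        else np.empty(0)
    )
    accepted_exo: list[float] = []
    lo_m, hi_m = config.exochemical_mass_range
    clearance = config.exochemical_clearance_ppm
    while sum(r["kind"] == "exochemical" for r in rows) < config.n_exochemicals:
        mass = rng.uniform(lo_m, hi_m)
        near_known = known.size and np.min(np.abs(known - mass)) / mass * 1e6 < clearance
        near_exo = accepted_exo and min(abs(m - mass) for m in accepted_exo) / mass * 1e6 < clearance
        if near_known or near_exo:
            continue
        accepted_exo.append(mass)
        base = rng.normal(config.log10_mean_abundance, config.log10_sd_abundance)
        means = {s: 10.0 ** (base + rng.normal(0.0, config.pig_run_log10_sd)) for s in samples}
        rows.append(
            {
                "kind": "exochemical",
                "compound_id": "",
                "neutral_mass_da": mass,
                "rt_min": rng.uniform(*config.exochemical_rt_range),
                "ion_mode": "positive" if rng.random() < config.positive_mode_fraction else "negative",
                "odd_parity": nitrogen_parity(mass).is_odd,
                "means": means,
            }
        )

    # --- targeted spike-ins at anchor retention times
    spike_map: dict[str, tuple[str, int]] = {}
    for spec in config.spikes:
        formula = _spike_formula(spec)
        mass = monoisotopic_mass(formula) * (1.0 + rng.uniform(-1, 1) * 0.5e-6)
        rows.append(
            {
                "kind": "spike",
                "compound_id": "",
                "neutral_mass_da": mass,
                "rt_min": spec.rt_min,
                "ion_mode": "negative",
                "odd_parity": formula_nitrogen_parity(formula),
                "means": dict(spec.abundances),
                "spike": (spec.family, spec.n),
            }
        )

    # --- calibrate per-sample odd-mass abundance shares to the RN targets
    if config.rn_targets:
        for s in samples:
            target = config.rn_targets.get(s)
            if target is None:
                continue
            odd_sum = sum(r["means"][s] for r in rows if r["odd_parity"])
            even_sum = sum(r["means"][s] for r in rows if not r["odd_parity"])
            if odd_sum <= 0 or even_sum <= 0:
                continue
            t = target / 100.0
            factor = t * even_sum / ((1.0 - t) * odd_sum)
            for r in rows:
                if r["odd_parity"]:
                    r["means"][s] *= factor

    # --- realize the table
    width = len(str(len(rows))) + 1
    ids = [f"F{k + 1:0{width}d}" for k in range(len(rows))]
    replicates = list(range(1, config.replicates + 1))
    columns = pd.MultiIndex.from_product([samples, replicates], names=["sample", "replicate"])
    abundance = np.empty((len(rows), len(columns)))
    for i, r in enumerate(rows):
        for j, (s, _rep) in enumerate(columns):
            mean = r["means"][s]
            if config.shot_noise:
                ions = mean / config.iu_per_ion
                abundance[i, j] = rng.poisson(ions) * config.iu_per_ion
            else:
                abundance[i, j] = mean
    features = pd.DataFrame(
        {
            "neutral_mass_da": [r["neutral_mass_da"] for r in rows],
            "rt_min": [r["rt_min"] for r in rows],
            "ion_mode": [r["ion_mode"] for r in rows],
        },
        index=pd.Index(ids, name="feature_id"),
    )
    table = FeatureTable(
        features=features,
        abundances=pd.DataFrame(abundance, index=features.index, columns=columns),
        provenance=f"synthetic seed={config.seed}",
    )

    # --- ground truth
    per_feature = pd.DataFrame(
        {
            "kind": [r["kind"] for r in rows],
            "compound_id": [r["compound_id"] for r in rows],
            "odd_parity": [r["odd_parity"] for r in rows],
            **{f"true_{s}": [r["means"][s] for r in rows] for s in samples},
        },
        index=features.index,
    )
    true_rn = {}
    true_rn_identified = {}
    for s in samples:
        col = per_feature[f"true_{s}"]
        total = float(col.sum())
        odd = float(col[per_feature["odd_parity"]].sum())
        true_rn[s] = 100.0 * odd / total
        ident = per_feature["kind"] == "metabolite"
        total_i = float(col[ident].sum())
        odd_i = float(col[ident & per_feature["odd_parity"]].sum())
        true_rn_identified[s] = 100.0 * odd_i / total_i if total_i > 0 else float("nan")
    sys_names = list(dict.fromkeys(systems.values()))
    sums = {
        sy: per_feature[[f"true_{s}" for s in samples if systems[s] == sy]].sum(axis=1) for sy in sys_names
    }
    hc_ids, lc_ids = set(), set()
    for fid in per_feature.index:
        hc_ab, lc_ab = float(sums["HC"][fid]), float(sums["LC"][fid])
        if max(hc_ab, lc_ab) > 10_000.0:
            if lc_ab == 0 or hc_ab / lc_ab >= 5.0:
                hc_ids.add(fid)
            if hc_ab == 0 or lc_ab / hc_ab >= 5.0:
                lc_ids.add(fid)
    spike_map = {
        ids[i]: rows[i]["spike"] for i in range(len(rows)) if rows[i]["kind"] == "spike"
    }
    truth = GroundTruth(
        per_feature=per_feature,
        true_rn=true_rn,
        true_rn_identified=true_rn_identified,
        hc_enriched_ids=frozenset(hc_ids),
        lc_enriched_ids=frozenset(lc_ids),
        spike_features=spike_map,
    )
    return table, truth


def simulate_metabolome(config: GeneratorConfig) -> SimulationBundle:
    """Run the whole metabolome generator off one seeded stream."""
    rng = config.rng()
    library, lib_truth = generate_library(config, rng)
    standards = generate_rt_standards(config, rng)
    table, truth = generate_feature_tables(config, library, lib_truth, rng)
    return SimulationBundle(
        config=config, library=library, library_truth=lib_truth, standards=standards, table=table, truth=truth
    )


def generate_metagenome_tables(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[GenomeBin], pd.DataFrame, pd.DataFrame, MetagenomeTruth]:
    """Bin table, gene-count table, sizes table, and community ground truth."""
    rng = config.rng() if rng is None else rng
    samples = list(config.samples)
    for s in samples:
        if s not in config.metagenome_sizes:
            raise KeyError(f"no metagenome size configured for sample {s!r}")
    frac = pd.DataFrame(
        {s: [dict(b.fractions).get(s, 0.0) for b in config.bins] for s in samples},
        index=[b.bin_id for b in config.bins],
    )
    over = frac.sum(axis=0) > 1.0 + 1e-9
    if over.any():
        raise ValueError(f"community fractions exceed 1 in samples: {list(frac.columns[over])}")

    bins: list[GenomeBin] = []
    for b in config.bins:
        coverage = {}
        for s in samples:
            _reads, bases = config.metagenome_sizes[s]
            noise = np.exp(rng.normal(0.0, config.coverage_noise_sd)) if config.coverage_noise_sd > 0 else 1.0
            coverage[s] = dict(b.fractions).get(s, 0.0) * bases / b.total_length * noise
        bins.append(
            GenomeBin(
                bin_id=b.bin_id,
                site=b.site,
                contig_count=b.contig_count,
                total_length=b.total_length,
                coverage=coverage,
                gene_annotations=frozenset(b.genes),
                recruitment_label=b.recruitment_label,
            )
        )

    genes = sorted({g for b in config.bins for g in b.genes})
    counts = pd.DataFrame(0.0, index=genes, columns=samples)
    for b, gb in zip(config.bins, bins):
        for g in b.genes:
            for s in samples:
                counts.loc[g, s] += gb.coverage[s] * config.gene_length_bp / config.mean_read_length
    counts = counts.round().astype(int)

    sizes = pd.DataFrame(
        {
            "total_reads": [config.metagenome_sizes[s][0] for s in samples],
            "total_bases": [config.metagenome_sizes[s][1] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )

    truth_fractions: dict[tuple[str, str], float] = {}
    for pid, definition in DEFAULT_PATHWAYS.items():
        for s in samples:
            total = 0.0
            for b in config.bins:
                probe = GenomeBin(b.bin_id, b.site, b.contig_count or 1, b.total_length, {}, frozenset(b.genes))
                if call_pathway(probe, definition).present:
                    total += dict(b.fractions).get(s, 0.0)
            truth_fractions[(pid, s)] = 100.0 * total
    return bins, counts, sizes, MetagenomeTruth(cell_fraction_percent=truth_fractions, bin_fractions=frac)


def simulate_metagenome(config: GeneratorConfig):
    return generate_metagenome_tables(config, config.rng())


def write_all(config: GeneratorConfig, outdir) -> dict[str, str]:
    """Emit every pipeline input plus a ground-truth subdirectory.

    Returns a name -> path map of everything written.  The raw observation
    file explodes the aligned table back into per-replicate rows so the
    alignment stage can be exercised end to end.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)

    bundle = simulate_metabolome(config)
    bins, counts, sizes, meta_truth = generate_metagenome_tables(config, config.rng())

    paths: dict[str, str] = {}

    def record(name: str, path: Path) -> Path:
        paths[name] = str(path)
        return path

    write_compound_library(bundle.library, record("library", outdir / "library.tsv"))
    X, y = bundle.standards
    standards = pd.DataFrame(X, columns=[f"d{k + 1}" for k in range(X.shape[1])])
    standards.insert(0, "standard_id", [f"STD{i + 1:03d}" for i in range(len(standards))])
    standards["observed_rt_min"] = y
    standards.to_csv(record("standards", outdir / "rt_standards.tsv"), sep="\t", index=False)

    write_feature_table(bundle.table, record("features", outdir / "features.tsv"))
    raw = bundle.table.to_long().drop(columns=["feature_id"])
    raw.to_csv(record("raw_features", outdir / "raw_features.tsv"), sep="\t", index=False)

    write_bin_table(bins, record("bins", outdir / "bins.tsv"))
    long_counts = counts.reset_index().melt(id_vars="index", var_name="sample", value_name="count")
    long_counts = long_counts.rename(columns={"index": "gene"})
    long_counts.to_csv(record("gene_counts", outdir / "gene_counts.tsv"), sep="\t", index=False)
    sizes.reset_index().to_csv(record("sizes", outdir / "metagenome_sizes.tsv"), sep="\t", index=False)
    write_pathway_definitions(DEFAULT_PATHWAYS, record("pathways", outdir / "pathways.yaml"))

    bundle.truth.per_feature.reset_index().to_csv(record("truth_per_feature", truth_dir / "per_feature.tsv"), sep="\t", index=False)
    summary = {
        "true_rn_percent": bundle.truth.true_rn,
        "true_rn_identified_percent": bundle.truth.true_rn_identified,
        "hc_enriched_count": len(bundle.truth.hc_enriched_ids),
        "lc_enriched_count": len(bundle.truth.lc_enriched_ids),
        "spike_features": {k: list(v) for k, v in bundle.truth.spike_features.items()},
        "cell_fraction_percent": {f"{p}:{s}": v for (p, s), v in meta_truth.cell_fraction_percent.items()},
        "seed": config.seed,
    }
    with open(record("truth_summary", truth_dir / "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return paths
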