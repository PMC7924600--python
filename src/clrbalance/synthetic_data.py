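"""Synthetic longitudinal cohorts with known planted truth.

The generator emulates the data structure of a two-cohort microbiome-
metabolome study: critically-ill patients sampled at 1-4 weekly time points
plus single-sample healthy controls.  Taxon abundances follow a logistic-
normal model — multivariate normal in log space with a per-patient random
intercept — and read counts are drawn multinomially at a sampled
sequencing depth, so the data inherit exactly the compositional structure
the clr-based analyses assume.  Three kinds of effects can be planted and
are recorded in a :class:`SyntheticTruth` for later scoring:

* a group-discriminating balance: the patient group's log abundances are
  shifted along the balance's unit clr contrast, moving the balance value
  by exactly the configured amount;
* a longitudinal slope: one taxon's log abundance tracks a neurological
  score with a patient random intercept;
* metabolite couplings: serum concentrations linear in the balance value
  plus patient intercept and noise, censored at the limit of detection.

Defaults mirror the emulated study: 44 patients (18 with one sample, 16
with two, 7 with three, 3 with four; 83 samples) and 20 controls, 150
taxa, positive/negative clinical dynamics split 15/29, an 11-metabolite
serum panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metabolites import MetabolitePanel, censor_lod
from .tables_io import CountTable, MetaboliteTable, SampleMetadata, parse_lineage

DEFAULT_TIMEPOINT_COUNTS = {1: 18, 2: 16, 3: 7, 4: 3}
DEFAULT_DYNAMICS_SPLIT = (15, 29)  # positive, negative
DEFAULT_DIAGNOSES = {"stroke": 16, "tbi": 13, "neurosurgery": 12, "anoxia": 3}

#: typical panel medians in µM used as baseline concentrations
DEFAULT_METABOLITE_BASE = {
    "PhLA": 0.3, "PhPA": 0.6, "PhAA": 0.3, "p-HPhAA": 0.7, "p-HPhPA": 0.3,
    "p-HPhLA": 0.8, "BA": 0.5, "p-HBA": 0.3, "HVA": 0.3, "SA": 6.3, "FA": 0.8,
}


def make_taxonomy(n_taxa: int) -> list[str]:
    """Deterministic species-level lineage strings for ``n_taxa`` taxa.

    Species nest 3-per-genus, genera 3-per-family, families 3-per-order, so
    rank aggregation is non-trivial; a slash ambiguity set and an ``_u``
    unclassified species are woven in periodically to exercise the naming
    conventions.
    """
    ids = []
    for i in range(n_taxa):
        g, f = i // 3, i // 9
        o, c, p = i // 27, i // 54, i // 108
        genus = (f"Genus{g:03d}a/Genus{g:03d}b" if g % 7 == 3
                 else f"Genus{g:03d}")
        if i % 3 == 2:
            species = genus + "_u"
        else:
            species = f"Species{i:04d}"
        ids.append(";".join([
            "Bacteria", f"Phylum{p:02d}", f"Class{c:02d}", f"Order{o:02d}",
            f"Family{f:03d}", genus, species]))
    return ids


@dataclass(frozen=True)
class PlantedBalance:
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    shift: float = 2.0  # log-scale balance-value difference, patients - controls


@dataclass(frozen=True)
class PlantedSlope:
    taxon: str
    outcome: str = "nihss"
    slope: float = 0.3
    intercept_sd: float = 1.0
    residual_sd: float = 0.5


@dataclass(frozen=True)
class MetaboliteCoupling:
    metabolite: str
    coefficient: float = 1.0  # µM per unit balance value
    noise_sd: float = 0.5
    lod: float = 0.1


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-shape parameters and planted effects; ``seed`` is mandatory."""

    seed: int
    n_patients: int = 44
    n_controls: int = 20
    timepoint_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINT_COUNTS))
    n_taxa: int = 150
    depth_range: tuple[int, int] = (10_000, 50_000)
    planted_balance: PlantedBalance | None = None
    planted_slope: PlantedSlope | None = None
    metabolite_couplings: tuple[MetaboliteCoupling, ...] = ()
    clr_taxon_sd: float = 1.5
    sample_noise_sd: float = 0.7
    patient_effect_sd: float = 0.4
    metabolite_intercept_sd: float = 0.3
    dynamics_split: tuple[int, int] = DEFAULT_DYNAMICS_SPLIT

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0 or self.n_taxa < 2:
            raise ValueError("cohort sizes must be positive")
        if sum(self.timepoint_counts.values()) != self.n_patients:
            raise ValueError("time-point distribution must cover all patients")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 1:
            raise ValueError("invalid depth range")

    @property
    def taxon_ids(self) -> list[str]:
        return make_taxonomy(self.n_taxa)

    def validate_planted(self) -> None:
        taxa = set(self.taxon_ids)
        for planted in (self.planted_balance,):
            if planted is not None:
                missing = (set(planted.numerator)
                           | set(planted.denominator)) - taxa
                if missing:
                    raise ValueError(f"planted taxa not in taxonomy: "
                                     f"{sorted(missing)}")
        if self.planted_slope is not None and self.planted_slope.taxon not in taxa:
            raise ValueError(
                f"planted slope taxon not in taxonomy: {self.planted_slope.taxon}")


def default_config(seed: int, shift: float = 2.0, slope: float = 0.3,
                   coupling: float = 1.0, **overrides) -> SyntheticCohortConfig:
    """Study-default configuration with one planted balance (first two
    species), one planted NIHSS slope and one coupled metabolite (PhPA)."""
    taxa = make_taxonomy(overrides.get("n_taxa", 150))
    cfg = SyntheticCohortConfig(
        seed=seed,
        planted_balance=PlantedBalance((taxa[0],), (taxa[3],), shift=shift),
        planted_slope=PlantedSlope(taxon=taxa[6], slope=slope),
        metabolite_couplings=(
            MetaboliteCoupling("PhPA", coefficient=coupling),),
        **overrides,
    )
    cfg.validate_planted()
    return cfg


@dataclass
class SyntheticTruth:
    """Planted effects, serialized beside the data; scores recovery."""

    balance_numerator: list[str] = field(default_factory=list)
    balance_denominator: list[str] = field(default_factory=list)
    balance_shift: float = 0.0
    slope_taxon: str | None = None
    slope_outcome: str | None = None
    slope: float = 0.0
    couplings: list[dict] = field(default_factory=list)
    seed: int = 0

    @property
    def planted_members(self) -> set[tuple[str, str]]:
        out = {(t, "numerator") for t in self.balance_numerator}
        out |= {(t, "denominator") for t in self.balance_denominator}
        return out

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticCohort:
    counts: CountTable
    metabolites: MetaboliteTable
    metadata: SampleMetadata
    truth: SyntheticTruth


def _balance_contrast(taxa: list[str], num: tuple[str, ...],
                      den: tuple[str, ...]) -> np.ndarray:
    """Unit-norm clr contrast vector of a balance: adding ``delta * w`` to a
    sample's log abundances moves the balance value by exactly ``delta``."""
    r, s = len(num), len(den)
    c = np.sqrt(r * s / (r + s))
    w = np.zeros(len(taxa))
    idx = {t: i for i, t in enumerate(taxa)}
    for t in num:
        w[idx[t]] = c / r
    for t in den:
        w[idx[t]] = -c / s
    return w


def generate_cohort(cfg: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw one cohort; fully reproducible from ``cfg.seed``."""
    cfg.validate_planted()
    rng = np.random.default_rng(cfg.seed)
    taxa = cfg.taxon_ids

    # --- subjects and samples
    subjects, tp_counts = [], []
    i = 0
    for k in sorted(cfg.timepoint_counts):
        for _ in range(cfg.timepoint_counts[k]):
            i += 1
            subjects.append(f"P{i:03d}")
            tp_counts.append(k)
    controls = [f"H{j + 1:03d}" for j in range(cfg.n_controls)]

    pos_frac = cfg.dynamics_split[0] / sum(cfg.dynamics_split)
    n_pos = min(int(round(pos_frac * cfg.n_patients)), cfg.n_patients)
    dyn_pool = (["positive"] * n_pos
                + ["negative"] * (cfg.n_patients - n_pos))
    rng.shuffle(dyn_pool)
    diag_pool = []
    for d, k in DEFAULT_DIAGNOSES.items():
        diag_pool += [d] * k
    if len(diag_pool) >= cfg.n_patients:
        diag_pool = diag_pool[: cfg.n_patients]
    else:
        diag_pool += list(rng.choice(list(DEFAULT_DIAGNOSES), size=cfg.n_patients - len(diag_pool)))
    rng.shuffle(diag_pool)

    rows = []
    for subj, ntp, dyn, diag in zip(subjects, tp_counts, dyn_pool, diag_pool):
        nihss0 = int(rng.integers(8, 30))
        gcs0 = int(rng.integers(6, 16))
        rank0 = int(rng.integers(3, 6))
        riv0 = int(rng.integers(0, 9))
        abx = "yes" if rng.random() < 13 / 44 else "no"
        nutr = "tube" if rng.random() < 23 / 44 else "oral"
        infection = "yes" if rng.random() < 13 / 44 else "no"
        drift = -2 if dyn == "positive" else 2
        for t in range(1, ntp + 1):
            nihss = int(np.clip(nihss0 + drift * (t - 1)
                                + rng.integers(-1, 2), 0, 42))
            rows.append(dict(
                sample_id=f"{subj}_t{t}", subject_id=subj, time_point=t,
                cohort="CCI", dynamics=dyn, diagnosis=diag,
                nihss=nihss,
                gcs=int(np.clip(gcs0 - drift // 2 * (t - 1), 3, 15)),
                rankin=int(np.clip(rank0 + (1 if dyn == "negative" and t > 2
                                            else 0), 1, 5)),
                rivermead=int(np.clip(riv0 - drift * (t - 1) // 2, 0, 15)),
                antibiotics=abx, nutrition=nutr, infection=infection,
            ))
    for subj in controls:
        rows.append(dict(
            sample_id=f"{subj}_t1", subject_id=subj, time_point=1,
            cohort="healthy", dynamics=np.nan, diagnosis=np.nan,
            nihss=np.nan, gcs=np.nan, rankin=np.nan, rivermead=np.nan,
            antibiotics="no", nutrition="oral", infection="no",
        ))
    meta_df = pd.DataFrame(rows).set_index("sample_id")
    all_subjects = subjects + controls
    n_samples = len(meta_df)

    # --- log-abundance model
    mu = rng.normal(0.0, cfg.clr_taxon_sd, size=cfg.n_taxa)
    patient_effect = {s: rng.normal(0.0, cfg.patient_effect_sd, size=cfg.n_taxa)
                      for s in all_subjects}
    Z = np.empty((n_samples, cfg.n_taxa))
    for k, (sid, row) in enumerate(meta_df.iterrows()):
        Z[k] = (mu + patient_effect[row["subject_id"]]
                + rng.normal(0.0, cfg.sample_noise_sd, size=cfg.n_taxa))
    is_cci = (meta_df["cohort"] == "CCI").to_numpy()

    if cfg.planted_balance is not None and cfg.planted_balance.shift != 0:
        w = _balance_contrast(taxa, cfg.planted_balance.numerator,
                              cfg.planted_balance.denominator)
        Z[is_cci] += cfg.planted_balance.shift * w

    if cfg.planted_slope is not None and cfg.planted_slope.slope != 0:
        ps = cfg.planted_slope
        j = taxa.index(ps.taxon)
        out_vals = pd.to_numeric(meta_df[ps.outcome], errors="coerce")
        centred = out_vals - out_vals.mean()
        b = {s: rng.normal(0.0, ps.intercept_sd) for s in all_subjects}
        for k, (sid, row) in enumerate(meta_df.iterrows()):
            x = centred.iloc[k]
            if np.isfinite(x):
                Z[k, j] = (mu[j] + ps.slope * x + b[row["subject_id"]]
                           + rng.normal(0.0, ps.residual_sd))

    # --- multinomial counts at a sampled depth
    depths = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1,
                          size=n_samples)
    P = np.exp(Z - Z.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, cfg.n_taxa), dtype=np.int64)
    for k in range(n_samples):
        counts[k] = rng.multinomial(depths[k], P[k])
    count_df = pd.DataFrame(counts.T, index=taxa, columns=meta_df.index)
    count_df.index.name = "taxon_id"
    lineages = {t: parse_lineage(t) for t in taxa}
    table = CountTable(count_df, rank="species", lineages=lineages)

    # --- metabolites linearly coupled to the realized balance value
    panel = MetabolitePanel()
    if cfg.planted_balance is not None:
        w = _balance_contrast(taxa, cfg.planted_balance.numerator,
                              cfg.planted_balance.denominator)
        bal_vals = np.log(P) @ w
        bal_vals = bal_vals - bal_vals.mean()
    else:
        bal_vals = np.zeros(n_samples)
    coupled = {c.metabolite: c for c in cfg.metabolite_couplings}
    conc = pd.DataFrame(index=meta_df.index, columns=list(panel.names),
                        dtype=float)
    flags = pd.DataFrame(False, index=meta_df.index, columns=list(panel.names))
    m_int = {s: rng.normal(0.0, cfg.metabolite_intercept_sd)
             for s in all_subjects}
    for m in panel.names:
        base = DEFAULT_METABOLITE_BASE.get(m, 0.5)
        cpl = coupled.get(m)
        coeff = cpl.coefficient if cpl is not None else 0.0
        noise_sd = cpl.noise_sd if cpl is not None else 0.3
        lod = cpl.lod if cpl is not None else panel.lod_for(m)
        raw = (base + coeff * bal_vals
               + np.array([m_int[s] for s in meta_df["subject_id"]])
               + rng.normal(0.0, noise_sd, size=n_samples))
        for k, sid in enumerate(meta_df.index):
            v, fl = censor_lod(max(raw[k], 0.0), lod)
            conc.loc[sid, m] = v
            flags.loc[sid, m] = fl
    metab = MetaboliteTable(conc, flags)

    truth = SyntheticTruth(seed=cfg.seed)
    if cfg.planted_balance is not None and cfg.planted_balance.shift != 0:
        truth.balance_numerator = list(cfg.planted_balance.numerator)
        truth.balance_denominator = list(cfg.planted_balance.denominator)
        truth.balance_shift = cfg.planted_balance.shift
    if cfg.planted_slope is not None and cfg.planted_slope.slope != 0:
        truth.slope_taxon = cfg.planted_slope.taxon
        truth.slope_outcome = cfg.planted_slope.outcome
        truth.slope = cfg.planted_slope.slope
    truth.couplings = [
        {"metabolite": c.metabolite, "coefficient": c.coefficient,
         "noise_sd": c.noise_sd, "lod": c.lod}
        for c in cfg.metabolite_couplings if c.coefficient != 0]
    return SyntheticCohort(table, metab, SampleMetadata(meta_df), truth)


def generate_null_cohort(cfg: SyntheticCohortConfig) -> SyntheticCohort:
    """Same generative process with every planted effect zeroed out."""
    null_cfg = replace(
        cfg,
        planted_balance=(replace(cfg.planted_balance, shift=0.0)
                         if cfg.planted_balance else None),
        planted_slope=(replace(cfg.planted_slope, slope=0.0)
                       if cfg.planted_slope else None),
        metabolite_couplings=tuple(
            replace(c, coefficient=0.0) for c in cfg.metabolite_couplings),
    )
    return generate_cohort(null_cfg)


def simulate_longitudinal_feature(n_subjects: int, n_timepoints: int,
                                  slope: float, intercept_sd: float,
                                  residual_sd: float, seed,
                                  outcome_sd: float = 1.0):
    """Direct random-intercept simulation for mixed-model checks.

    Returns ``(feature, outcome, subject_ids)`` arrays with
    feature = slope * outcome + b_subject + noise.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    subj = np.repeat(np.arange(n_subjects), n_timepoints)
    b = rng.normal(0.0, intercept_sd, size=n_subjects)
    x = rng.normal(0.0, outcome_sd, size=subj.size)
    yv = slope * x + b[subj] + rng.normal(0.0, residual_sd, size=subj.size)
    return yv, x, subj


def score_recovery(truth: SyntheticTruth, result,
                   slope_estimates: dict[str, float] | None = None) -> dict:
    """Score a selection result (and optional slope estimates) against the
    planted truth: membership precision/recall, planted-taxon
    reproducibility, slope bias."""
    planted = truth.planted_members
    selected = ({(t, "numerator") for t in result.balance.numerator}
                | {(t, "denominator") for t in result.balance.denominator})
    tp = len(planted & selected)
    precision = tp / len(selected) if selected else 0.0
    recall = tp / len(planted) if planted else 1.0
    rep = result.reproducibility
    planted_rep = {
        f"{t} ({side})": float(
            rep.loc[(rep["taxon"] == t) & (rep["side"] == side), "percent"].sum())
        for (t, side) in sorted(planted)}
    out = {
        "membership_precision": precision,
        "membership_recall": recall,
        "planted_taxon_reproducibility": planted_rep,
    }
    if slope_estimates is not None and truth.slope_taxon is not None:
        est = slope_estimates.get(truth.slope_taxon, np.nan)
        out["slope_estimate"] = float(est)
        out["slope_bias"] = float(est - truth.slope)
    return out
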