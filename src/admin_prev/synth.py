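"""Synthetic generator for regional administrative healthcare data.

Emulates the data environment of a population-based prevalence study built
on three routinely collected sources — hospital discharge records carrying a
disease ICD code, disease-specific drug prescriptions, and outpatient
contacts under a disease-specific co-payment exemption — linked by an
anonymised person identifier, together with a single-centre clinical
registry covering a subsample of cases.

Every downstream stage (linkage, validation, imputation, standardisation,
regression, capture–recapture) can therefore be tested against known ground
truth without any external data.  Capture of true cases by the three sources
follows a log-linear cell-probability model over {0,1}^3 so that the
generator's truth lives in exactly the model family the capture–recapture
stage fits: main-effect logits are the per-source capture probabilities and
pairwise interactions (log-odds scale) encode source dependence, zero
meaning independence.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SOURCES = ("hospital", "drug", "outpatient")

#: placeholder clinical codes: ICD-9-CM 340 (the disease's discharge code),
#: a generic disease-modifying-therapy marker, and exemption code 046.
SOURCE_CODES = {"hospital": "340", "drug": "DMT", "outpatient": "046"}

AGE_BANDS: tuple[str, ...] = tuple(
    f"{5 * i}-{5 * i + 4}" for i in range(17)
) + ("85+",)

# Approximate age structure of a Southern-Italian regional population on
# 1 January 2018 (5-year bands 0-4 ... 85+), normalised to sum to 1.
_RAW_AGE = np.array(
    [4.4, 4.9, 5.2, 5.5, 5.8, 5.9, 6.0, 6.4, 7.2, 7.6,
     7.6, 6.9, 6.0, 5.4, 4.6, 4.0, 3.2, 2.4]
)
DEFAULT_AGE_DISTRIBUTION: tuple[float, ...] = tuple(_RAW_AGE / _RAW_AGE.sum())

#: the seven Local Health Authorities of the region, with approximate
#: population shares, and their grouping into five provinces.
DEFAULT_AREAS = ("AV", "BN", "CE", "NA1", "NA2", "NA3", "SA")
_RAW_AREA_SHARES = np.array([0.072, 0.048, 0.158, 0.165, 0.177, 0.187, 0.189])
DEFAULT_AREA_SHARES: tuple[float, ...] = tuple(
    _RAW_AREA_SHARES / _RAW_AREA_SHARES.sum()
)
AREA_PROVINCE = {
    "AV": "Avellino",
    "BN": "Benevento",
    "CE": "Caserta",
    "NA1": "Napoli",
    "NA2": "Napoli",
    "NA3": "Napoli",
    "SA": "Salerno",
}

# Relative disease risk by registration area, reproducing the documented
# provincial gradient (lowest in the metropolitan province, highest in
# Salerno/Avellino); rescaled internally so the marginal prevalence is
# exactly the configured rate.
DEFAULT_AREA_RELATIVE_RISK = {
    "AV": 1.26, "BN": 1.01, "CE": 0.92,
    "NA1": 0.89, "NA2": 0.89, "NA3": 0.89, "SA": 1.27,
}

# Per-source capture probabilities of a true case.  Jointly they give a
# detection probability of 1 - 0.55*0.16*0.30 = 97.4%, i.e. an expected
# 2.7% of cases missed by all three sources.
DEFAULT_CAPTURE_PROB = {"hospital": 0.45, "drug": 0.84, "outpatient": 0.70}

PAIRS = ("hospital:drug", "hospital:outpatient", "drug:outpatient")


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions: a regional population of
    5,826,860 on the prevalence day (1 January 2018), disease prevalence of
    90 per 100,000, a three-year study window, case demographics of 64.4%
    female with age 44.6 +/- 12.9 years, 2.5% missing birth years and 8.8%
    missing registration areas, and a clinical registry enrolling roughly
    27% of cases.
    """

    population_size: int = 5_826_860
    prevalence_per_100k: float = 90.0
    age_band_distribution: Sequence[float] = DEFAULT_AGE_DISTRIBUTION
    sex_ratio_female: float = 2_985_811 / 5_826_860
    case_female_fraction: float = 0.644
    case_age_mean: float = 44.6
    case_age_sd: float = 12.9
    capture_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAPTURE_PROB)
    )
    pairwise_dependence: Mapping[str, float] = field(default_factory=dict)
    extra_record_rate: float = 1.2
    nonresident_fraction: float = 0.02
    missing_birth_year_rate: float = 0.025
    missing_area_rate: float = 0.088
    mar_on_sex: bool = False
    registry_fraction: float = 1460 / 5362
    registry_capture_bias: float = 0.0
    false_positive_rate: float = 0.0
    n_areas: int = 7
    area_shares: Sequence[float] = DEFAULT_AREA_SHARES
    area_relative_risk: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AREA_RELATIVE_RISK)
    )
    study_window: tuple[int, int] = (2015, 2017)
    prevalence_year: int = 2018
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.prevalence_per_100k < 0:
            raise ValueError("prevalence_per_100k must be >= 0")
        dist = np.asarray(self.age_band_distribution, dtype=float)
        if dist.shape != (len(AGE_BANDS),):
            raise ValueError(
                f"age_band_distribution must have {len(AGE_BANDS)} entries"
            )
        if (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("age_band_distribution must be >=0 and sum to 1")
        for name in ("sex_ratio_female", "case_female_fraction",
                     "nonresident_fraction", "missing_birth_year_rate",
                     "missing_area_rate", "registry_fraction",
                     "false_positive_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if set(self.capture_prob) != set(SOURCES):
            raise ValueError(f"capture_prob must have keys {SOURCES}")
        for src, p in self.capture_prob.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"capture_prob[{src}] must be in (0, 1)")
        for pair in self.pairwise_dependence:
            if pair not in PAIRS:
                raise ValueError(f"pairwise_dependence key {pair!r} not in {PAIRS}")
        if self.n_areas < 1:
            raise ValueError("n_areas must be >= 1")
        shares = np.asarray(self.area_shares, dtype=float)
        if shares.shape != (self.n_areas,):
            raise ValueError("area_shares must have n_areas entries")
        if self.extra_record_rate < 0:
            raise ValueError("extra_record_rate must be >= 0")

    @property
    def area_labels(self) -> tuple[str, ...]:
        if self.n_areas == len(DEFAULT_AREAS):
            return DEFAULT_AREAS
        return tuple(f"A{i + 1}" for i in range(self.n_areas))


# ---------------------------------------------------------------------------
# population


def _draw_ages(rng: np.random.Generator, n: int,
               band_probs: np.ndarray) -> np.ndarray:
    """Ages drawn band-wise, uniform inside each 5-year band (85+ -> 85-99)."""
    band = rng.choice(len(AGE_BANDS), size=n, p=band_probs)
    low = band * 5
    width = np.where(band == len(AGE_BANDS) - 1, 15, 5)
    return low + rng.integers(0, 10_000, size=n) % width


def generate_population(config: SynthConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the person table with ground-truth case status.

    Case status is Bernoulli at the configured prevalence, modulated by the
    registration-area relative risks (rescaled so the marginal rate is
    preserved).  Case demographics are then redrawn from the case-specific
    sex and age distributions, leaving the overall population structure
    essentially unchanged (cases are <0.1% of persons).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.population_size
    labels = config.area_labels

    band_probs = np.asarray(config.age_band_distribution, dtype=float)
    age = _draw_ages(rng, n, band_probs)
    sex = np.where(rng.random(n) < config.sex_ratio_female, "F", "M")
    shares = np.asarray(config.area_shares, dtype=float)
    shares = shares / shares.sum()
    area_idx = rng.choice(config.n_areas, size=n, p=shares)
    resident = rng.random(n) >= config.nonresident_fraction

    rr = np.array([config.area_relative_risk.get(lab, 1.0) for lab in labels])
    mean_rr = float(shares @ rr)
    p_case = (config.prevalence_per_100k / 1e5) * rr[area_idx] / mean_rr
    is_case = rng.random(n) < p_case

    # case demographics override the population draw
    n_cases = int(is_case.sum())
    if n_cases:
        sex_case = np.where(
            rng.random(n_cases) < config.case_female_fraction, "F", "M"
        )
        age_case = np.clip(
            rng.normal(config.case_age_mean, config.case_age_sd, n_cases),
            0, 99,
        ).astype(int)
        sex[is_case] = sex_case
        age[is_case] = age_case

    persons = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1, dtype=np.int64),
            "sex": sex,
            "birth_year": pd.array(config.prevalence_year - age,
                                   dtype="Int32"),
            "area": pd.array([labels[i] for i in area_idx], dtype="string"),
            "resident": resident,
            "is_case": is_case,
        }
    )
    for src in SOURCES:
        persons[f"cap_{src}"] = np.zeros(n, dtype=np.int8)
    persons["in_registry"] = np.zeros(n, dtype=bool)
    return persons


# ---------------------------------------------------------------------------
# capture model


def capture_cell_probabilities(
    capture_prob: Mapping[str, float],
    pairwise_dependence: Mapping[str, float] | None = None,
) -> tuple[list[tuple[int, int, int]], np.ndarray]:
    """Cell probabilities of the log-linear capture model over {0,1}^3.

    log p(a,b,c) = const + a*logit(pA) + b*logit(pB) + c*logit(pC)
                   + ab*t_AB + ac*t_AC + bc*t_BC

    With all pairwise terms zero this is the independent product-Bernoulli
    model with marginals exactly ``capture_prob``; nonzero terms shift the
    marginals (the logits stay the main effects of the log-linear truth).
    """
    pairwise_dependence = pairwise_dependence or {}
    logits = [
        np.log(capture_prob[s] / (1.0 - capture_prob[s])) for s in SOURCES
    ]
    theta = [pairwise_dependence.get(p, 0.0) for p in PAIRS]
    patterns = list(itertools.product((0, 1), repeat=3))
    log_p = np.array(
        [
            a * logits[0] + b * logits[1] + c * logits[2]
            + a * b * theta[0] + a * c * theta[1] + b * c * theta[2]
            for a, b, c in patterns
        ]
    )
    log_p -= log_p.max()
    p = np.exp(log_p)
    return patterns, p / p.sum()


def assign_capture(persons: pd.DataFrame, config: SynthConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a source-capture pattern for every true case (in place).

    Non-cases keep the empty pattern unless ``false_positive_rate`` > 0, in
    which case that fraction of non-cases acquires a single record in one
    source chosen uniformly (a knob for stressing positive predictive value).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    patterns, probs = capture_cell_probabilities(
        config.capture_prob, config.pairwise_dependence
    )
    pattern_arr = np.array(patterns, dtype=np.int8)

    case_idx = np.flatnonzero(persons["is_case"].to_numpy())
    draw = rng.choice(len(patterns), size=case_idx.size, p=probs)
    for j, src in enumerate(SOURCES):
        col = persons[f"cap_{src}"].to_numpy().copy()
        col[case_idx] = pattern_arr[draw, j]
        persons[f"cap_{src}"] = col

    if config.false_positive_rate > 0:
        noncase_idx = np.flatnonzero(~persons["is_case"].to_numpy())
        hit = noncase_idx[
            rng.random(noncase_idx.size) < config.false_positive_rate
        ]
        which = rng.integers(0, len(SOURCES), size=hit.size)
        for j, src in enumerate(SOURCES):
            col = persons[f"cap_{src}"].to_numpy().copy()
            col[hit[which == j]] = 1
            persons[f"cap_{src}"] = col
    return persons


# ---------------------------------------------------------------------------
# record emission


def emit_records(persons: pd.DataFrame, config: SynthConfig,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Expand capture patterns into event-level administrative records.

    A captured source yields ``1 + Poisson(extra_record_rate)`` rows for
    that person, each with a year uniform in the study window and the
    source's placeholder clinical code.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    y0, y1 = config.study_window
    frames = []
    for src in SOURCES:
        captured = persons.loc[persons[f"cap_{src}"] == 1,
                               ["person_id", "area"]]
        k = captured.shape[0]
        if k == 0:
            continue
        counts = 1 + rng.poisson(config.extra_record_rate, size=k)
        rep = captured.loc[captured.index.repeat(counts)].reset_index(drop=True)
        frames.append(
            pd.DataFrame(
                {
                    "person_id": rep["person_id"].to_numpy(),
                    "source": src,
                    "year": rng.integers(y0, y1 + 1, size=counts.sum()),
                    "code": SOURCE_CODES[src],
                    "area": rep["area"].to_numpy(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["person_id", "source", "year", "code", "area"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# missingness


def inject_missingness(persons: pd.DataFrame, config: SynthConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Return a copy with birth_year and area masked at the configured rates.

    Default mechanism is MCAR.  With ``mar_on_sex`` the masking probability
    is 1.5x for females and rescaled for males so the marginal rate is kept,
    giving a missing-at-random mechanism for imputation stress tests.  The
    input frame is never modified: it is the ground truth.
    """
    for name in ("missing_birth_year_rate", "missing_area_rate"):
        rate = getattr(config, name)
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    masked = persons.copy()
    n = len(masked)
    if config.mar_on_sex:
        is_f = (masked["sex"] == "F").to_numpy()
        pf = is_f.mean()
        scale = np.where(is_f, 1.5, (1 - 1.5 * pf) / (1 - pf) if pf < 1 else 1.0)
    else:
        scale = np.ones(n)
    mask_by = rng.random(n) < config.missing_birth_year_rate * scale
    mask_ar = rng.random(n) < config.missing_area_rate * scale
    by = masked["birth_year"].copy()
    by[mask_by] = pd.NA
    masked["birth_year"] = by
    ar = masked["area"].copy()
    ar[mask_ar] = pd.NA
    masked["area"] = ar
    return masked


# ---------------------------------------------------------------------------
# registry


def sample_registry(persons: pd.DataFrame, fraction: float,
                    rng: np.random.Generator | None = None,
                    capture_bias: float = 0.0,
                    seed: int | None = None) -> np.ndarray:
    """Sample case ids into the single-centre clinical registry.

    The registry is a single regional clinical centre, so only resident
    cases are eligible.  Draws ``round(fraction * n_cases)`` of them without
    replacement.  With
    ``capture_bias`` w > 0 a case captured by at least one source gets
    sampling weight 1 + w relative to an undetected case; the default 0
    makes registry membership independent of administrative capture.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(4 if seed is None else seed)
    cases = persons.loc[persons["is_case"] & persons["resident"]]
    n_take = int(round(fraction * len(cases)))
    if n_take == 0:
        return np.array([], dtype=np.int64)
    captured = (
        cases[[f"cap_{s}" for s in SOURCES]].to_numpy().sum(axis=1) > 0
    )
    w = 1.0 + capture_bias * captured
    p = w / w.sum()
    ids = cases["person_id"].to_numpy()
    return np.sort(rng.choice(ids, size=n_take, replace=False, p=p))


# ---------------------------------------------------------------------------
# orchestration and I/O


def generate_study(config: SynthConfig) -> dict:
    """Run the full generator and return all study artefacts.

    Returns a dict with keys ``persons_truth`` (complete table),
    ``persons`` (with missingness injected), ``records`` (event rows),
    and ``registry_ids``.  All randomness flows from ``config.seed``
    through independent spawned streams, so identical configs reproduce
    identical studies.
    """
    root = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(5)]
    persons = generate_population(config, streams[0])
    persons = assign_capture(persons, config, streams[1])
    registry_ids = sample_registry(
        persons, config.registry_fraction, streams[2],
        capture_bias=config.registry_capture_bias,
    )
    persons["in_registry"] = persons["person_id"].isin(registry_ids)
    truth = persons.copy()
    persons = inject_missingness(persons, config, streams[3])
    records = emit_records(persons, config, streams[4])
    return {
        "persons_truth": truth,
        "persons": persons,
        "records": records,
        "registry_ids": registry_ids,
    }


def write_study(study: dict, outdir: str | Path) -> dict[str, Path]:
    """Write the study to CSV files plus a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    records = study["records"]
    for src in SOURCES:
        p = outdir / f"{src}.csv"
        records.loc[records["source"] == src].to_csv(p, index=False)
        paths[src] = p
    p = outdir / "persons.csv"
    study["persons"].to_csv(p, index=False)
    paths["persons"] = p
    p = outdir / "registry.csv"
    pd.DataFrame({"person_id": study["registry_ids"]}).to_csv(p, index=False)
    paths["registry"] = p

    truth = study["persons_truth"]
    masked = study["persons"]
    masked_by = masked["birth_year"].isna() & truth["birth_year"].notna()
    masked_ar = masked["area"].isna() & truth["area"].notna()
    sidecar = {
        "n_persons": int(len(truth)),
        "n_cases": int(truth["is_case"].sum()),
        "n_registry": int(len(study["registry_ids"])),
        "masked_birth_year": {
            str(pid): int(v)
            for pid, v in zip(truth.loc[masked_by, "person_id"],
                              truth.loc[masked_by, "birth_year"])
        },
        "masked_area": {
            str(pid): str(v)
            for pid, v in zip(truth.loc[masked_ar, "person_id"],
                              truth.loc[masked_ar, "area"])
        },
    }
    p = outdir / "ground_truth.json"
    p.write_text(json.dumps(sidecar))
    paths["ground_truth"] = p
    return paths
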