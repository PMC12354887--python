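"""Synthetic longitudinal EHR cohorts with planted latent structure.

Real coded-EHR cohorts of the scale used for patient-embedding work are
access-restricted, so every downstream stage in this package is exercised on
simulated cohorts whose ground truth is known by construction.  The
generator plants, per patient:

* a latent disease subtype with its own comorbidity signature (a disjoint
  set of phecodes emitted in post-onset years), onset-age distribution and
  post-onset mortality hazard;
* a persistent per-patient code signature (a few codes recurring in ~90% of
  the patient's years) that carries patient identity for the siamese tasks;
* heavy-tailed (Zipf) background code usage with mild age structure, so the
  minimum-occurrence vocabulary filter and age-binned frequency matrix see
  realistic sparsity;
* a prodromal phase in which comorbidity codes appear at reduced rate in
  the years just before onset, emulating the pre-onset comorbidity
  divergence seen in real disease-progression data and giving the
  onset-prediction task a learnable signal.

Everything is a deterministic function of ``SimConfig`` (including its
seed): identical configs produce byte-identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ehr_io import DAYS_PER_YEAR, PhecodeMap, sort_events

DISEASE_CLASSES = (
    "circulatory system", "endocrine/metabolic", "genitourinary",
    "infectious diseases", "mental disorders", "neoplasms",
    "digestive", "respiratory",
)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults define the standard cohort used throughout the test-suite and
    acceptance runs: 3 subtypes with disjoint 5-phecode comorbidity
    signatures, strong post-onset emission (0.9/phecode/year), weaker
    prodromal emission, and subtype-ordered mortality hazards.
    """

    n_patients: int = 500
    vocab_size_dx: int = 60
    vocab_size_px: int = 20
    n_subtypes: int = 3
    followup_years_mean: float = 12.0
    max_followup_years: int = 25
    codes_per_year_mean: float = 8.0
    n_signature_codes_per_patient: int = 3
    signature_year_fraction: float = 0.9
    codes_per_phecode: int = 2
    index_phecode: str = "PH000"
    subtype_onset_age_means: tuple[float, ...] | None = None
    onset_age_sd: float = 5.0
    subtype_comorbidity_sets: tuple[tuple[str, ...], ...] | None = None
    emergent_code_prob: float = 0.9
    prodrome_years: int = 3
    prodrome_code_prob: float = 0.7
    mortality_hazard_per_subtype: tuple[float, ...] | None = None
    censoring_hazard: float = 0.06
    entry_age_low: int = 30
    entry_age_high: int = 60
    zipf_exponent: float = 1.3
    background_comorbidity_weight: float = 0.1
    episode_rate: float = 0.7          # new 2-year episodes per patient-year
    episode_codes_per_year: int = 2
    demographic_levels: dict[str, list[str]] = field(default_factory=lambda: {
        "gender": ["F", "M"],
        "race": ["R1", "R2", "R3"],
        "ethnicity": ["E1", "E2"],
        "site": ["S1", "S2", "S3"],
    })
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.vocab_size_dx < 1:
            raise ConfigurationError("empty diagnosis vocabulary")
        if self.n_subtypes < 1:
            raise ConfigurationError("n_subtypes must be >= 1")
        for name in ("emergent_code_prob", "prodrome_code_prob",
                     "signature_year_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.subtype_onset_age_means is None:
            self.subtype_onset_age_means = tuple(
                45.0 + 10.0 * k for k in range(self.n_subtypes))
        if self.mortality_hazard_per_subtype is None:
            self.mortality_hazard_per_subtype = tuple(
                0.03 * (1 + 2 * k) for k in range(self.n_subtypes))
        if self.subtype_comorbidity_sets is None:
            self.subtype_comorbidity_sets = self._default_comorbidity_sets()
        if len(self.subtype_onset_age_means) != self.n_subtypes:
            raise ConfigurationError("one onset-age mean per subtype required")
        if len(self.mortality_hazard_per_subtype) != self.n_subtypes:
            raise ConfigurationError("one mortality hazard per subtype required")
        if len(self.subtype_comorbidity_sets) != self.n_subtypes:
            raise ConfigurationError("one comorbidity set per subtype required")

    # -- vocabulary layout --------------------------------------------------
    def dx_codes(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.vocab_size_dx)]

    def px_codes(self) -> list[str]:
        return [f"X{i:04d}" for i in range(self.vocab_size_px)]

    def code_system(self, code: str) -> str:
        if code.startswith("X"):
            return "CPT4"
        return "ICD10" if int(code[1:]) % 2 == 0 else "ICD9"

    def n_phecodes(self) -> int:
        return math.ceil(self.vocab_size_dx / self.codes_per_phecode)

    def phecode_of(self, dx_index: int) -> str:
        return f"PH{dx_index // self.codes_per_phecode:03d}"

    def dx_codes_of_phecode(self, phecode: str) -> list[str]:
        j = int(phecode[2:])
        lo = j * self.codes_per_phecode
        hi = min(lo + self.codes_per_phecode, self.vocab_size_dx)
        return [f"D{i:03d}" for i in range(lo, hi)]

    def _default_comorbidity_sets(self, set_size: int = 5):
        n_phe = self.n_phecodes()
        needed = 1 + set_size * self.n_subtypes  # index phecode + disjoint sets
        if n_phe < needed:
            raise ConfigurationError(
                f"need >= {needed} phecodes for disjoint comorbidity sets, "
                f"have {n_phe}; increase vocab_size_dx")
        sets = []
        for k in range(self.n_subtypes):
            lo = 1 + k * set_size
            sets.append(tuple(f"PH{j:03d}" for j in range(lo, lo + set_size)))
        return tuple(sets)


@dataclass
class SimTruth:
    """Per-patient ground truth of the generated cohort."""

    table: pd.DataFrame  # patient_id, subtype, onset_age_years, death_age_years
    signature_codes: dict[str, list[str]]

    def write(self, path: str | Path) -> None:
        payload = {
            "patients": self.table.replace({np.nan: None}).to_dict("records"),
            "signature_codes": self.signature_codes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(table=pd.DataFrame(payload["patients"]),
                   signature_codes=payload["signature_codes"])


@dataclass
class CohortSummary:
    """Follow-up-year and codes-per-year distributions of a cohort."""

    followup_years: pd.Series          # patient_id -> n distinct event-years
    codes_per_year: pd.DataFrame       # patient_id, year_index, n_codes

    @property
    def total_events(self) -> int:
        return int(self.codes_per_year["n_codes"].sum()) \
            if len(self.codes_per_year) else 0


def generate_phecode_map(config: SimConfig) -> PhecodeMap:
    """Deterministic toy phecode map: every dx code -> exactly one phecode."""
    code_to_phecode = {f"D{i:03d}": config.phecode_of(i)
                       for i in range(config.vocab_size_dx)}
    phecode_class = {p: DISEASE_CLASSES[int(p[2:]) % len(DISEASE_CLASSES)]
                     for p in set(code_to_phecode.values())}
    return PhecodeMap(code_to_phecode, phecode_class)


def _age_day(year: int, rng: np.random.Generator) -> int:
    # ceil anchors the draw inside the floor(age/365.25) == year bin
    return int(np.ceil(year * DAYS_PER_YEAR)) + int(rng.integers(0, 365))


def generate_cohort(config: SimConfig):
    """Generate (events, demographics, survival, truth) for one cohort.

    Returns
    -------
    events : DataFrame [patient_id, age_days, code, code_system], sorted
    demographics : DataFrame [patient_id, birth_decade, gender, race,
        ethnicity, site]
    survival : DataFrame [patient_id, time_years, event] — index-disease
        cases only, time measured from onset, event=1 for observed death
    truth : SimTruth
    """
    rng = np.random.default_rng(config.seed)
    all_codes = config.dx_codes() + config.px_codes()
    n_codes = len(all_codes)

    # Zipf popularity over a seeded permutation; codes in the first third of
    # the permuted order age upward, the second third age downward.
    perm = rng.permutation(n_codes)
    base_w = (np.argsort(perm) + 1.0) ** (-config.zipf_exponent)
    # index-disease codes are emitted only through true onset, never as
    # background chatter: the phecode-defined cohort must equal the cases
    index_codes = set(config.dx_codes_of_phecode(config.index_phecode))
    base_w[[i for i, c in enumerate(all_codes) if c in index_codes]] = 0.0
    # comorbidity-set codes appear in background chatter only at reduced
    # weight: enough to act as label noise, not enough to drown the
    # planted subtype signatures
    comorb_codes = {c for phe_set in config.subtype_comorbidity_sets
                    for phe in phe_set
                    for c in config.dx_codes_of_phecode(phe)}
    comorb_idx = [i for i, c in enumerate(all_codes) if c in comorb_codes]
    base_w[comorb_idx] *= config.background_comorbidity_weight
    trend = np.zeros(n_codes)
    trend[perm[: n_codes // 3]] = 1.0
    trend[perm[n_codes // 3: 2 * n_codes // 3]] = -1.0

    def background_weights(age_year: int) -> np.ndarray:
        w = base_w * np.exp(trend * (age_year - 50.0) / 30.0)
        return w / w.sum()

    event_rows: list[tuple[str, int, str]] = []
    demo_rows, surv_rows, truth_rows = [], [], []
    signature_codes: dict[str, list[str]] = {}

    for p in range(config.n_patients):
        pid = f"PT{p:05d}"
        subtype = int(rng.integers(0, config.n_subtypes))
        demo = {"patient_id": pid,
                "birth_decade": int(rng.choice(np.arange(1930, 2000, 10)))}
        for key, levels in config.demographic_levels.items():
            demo[key] = str(rng.choice(levels))
        demo_rows.append(demo)

        n_years = 1 + int(rng.poisson(max(config.followup_years_mean - 1, 0)))
        n_years = min(n_years, config.max_followup_years)
        entry = int(rng.integers(config.entry_age_low, config.entry_age_high + 1))
        years = list(range(entry, entry + n_years))

        sig_pool = [c for c in all_codes if c not in index_codes]
        sig = list(rng.choice(sig_pool, size=min(
            config.n_signature_codes_per_patient, len(sig_pool)),
            replace=False))
        signature_codes[pid] = [str(c) for c in sig]
        n_sig_years = math.ceil(config.signature_year_fraction * n_years)

        onset_draw = rng.normal(config.subtype_onset_age_means[subtype],
                                config.onset_age_sd)
        onset_year = int(math.floor(onset_draw))
        is_case = years[0] <= onset_year <= years[-1]

        sig_years = {c: set(rng.choice(years, size=n_sig_years, replace=False))
                     for c in sig}

        # clinical episodes: a code flaring in two consecutive years, the
        # only within-patient signal that distinguishes adjacent years
        episode_codes: dict[int, list[str]] = {y: [] for y in years}
        for y in years[:-1]:
            if rng.random() < config.episode_rate:
                c = str(rng.choice(sig_pool))
                episode_codes[y].append(c)
                episode_codes[y + 1].append(c)

        for y in years:
            n_bg = rng.poisson(config.codes_per_year_mean)
            if n_bg:
                for c in rng.choice(all_codes, size=n_bg, replace=True,
                                    p=background_weights(y)):
                    event_rows.append((pid, _age_day(y, rng), str(c)))
            for c in sig:
                if y in sig_years[c]:
                    event_rows.append((pid, _age_day(y, rng), str(c)))
            for c in episode_codes[y]:
                for _ in range(config.episode_codes_per_year):
                    event_rows.append((pid, _age_day(y, rng), c))
            if is_case:
                comorb = config.subtype_comorbidity_sets[subtype]
                if y == onset_year or (y > onset_year and rng.random() < 0.5):
                    idx_code = config.dx_codes_of_phecode(config.index_phecode)[0]
                    event_rows.append((pid, _age_day(y, rng), idx_code))
                if y >= onset_year:
                    p_emit = config.emergent_code_prob
                elif y >= onset_year - config.prodrome_years:
                    p_emit = config.prodrome_code_prob
                else:
                    p_emit = 0.0
                if p_emit > 0:
                    for phe in comorb:
                        if rng.random() < p_emit:
                            c = rng.choice(config.dx_codes_of_phecode(phe))
                            event_rows.append((pid, _age_day(y, rng), str(c)))

        death_age = None
        if is_case:
            hazard = config.mortality_hazard_per_subtype[subtype]
            t_death = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
            t_cens = rng.exponential(1.0 / config.censoring_hazard) \
                if config.censoring_hazard > 0 else np.inf
            observed = t_death <= t_cens
            surv_rows.append({"patient_id": pid,
                              "time_years": float(min(t_death, t_cens)),
                              "event": int(observed)})
            if observed:
                death_age = onset_year + float(t_death)

        truth_rows.append({
            "patient_id": pid,
            "subtype": subtype,
            "onset_age_years": onset_year if is_case else None,
            "death_age_years": death_age,
        })

    events = pd.DataFrame(event_rows, columns=["patient_id", "age_days", "code"])
    if len(events):
        events["code_system"] = [config.code_system(c) for c in events["code"]]
        events = sort_events(events)
    else:
        events = pd.DataFrame(columns=["patient_id", "age_days", "code",
                                       "code_system"])
    demographics = pd.DataFrame(
        demo_rows, columns=["patient_id", "birth_decade",
                            *config.demographic_levels.keys()])
    survival = pd.DataFrame(surv_rows, columns=["patient_id", "time_years",
                                                "event"])
    truth = SimTruth(
        table=pd.DataFrame(truth_rows, columns=["patient_id", "subtype",
                                                "onset_age_years",
                                                "death_age_years"]),
        signature_codes=signature_codes,
    )
    return events, demographics, survival, truth


def generate_copy_cohort(n_patients: int = 200, n_years: int = 6,
                         vocab_size: int = 30, codes_per_patient: int = 5,
                         seed: int = 0) -> pd.DataFrame:
    """Deterministic-rule cohort: every patient repeats one fixed code set
    in every follow-up year, so year i+1 codes equal year i codes exactly.

    Used as a learnability oracle for the next-year objective.
    """
    rng = np.random.default_rng(seed)
    codes = [f"D{i:03d}" for i in range(vocab_size)]
    rows = []
    for p in range(n_patients):
        pid = f"PT{p:05d}"
        own = rng.choice(codes, size=codes_per_patient, replace=False)
        entry = int(rng.integers(30, 60))
        for y in range(entry, entry + n_years):
            for c in own:
                rows.append((pid, _age_day(y, rng), str(c), "ICD10"))
    return sort_events(pd.DataFrame(
        rows, columns=["patient_id", "age_days", "code", "code_system"]))


def summarize_cohort(events: pd.DataFrame) -> CohortSummary:
    """Per-patient follow-up-year counts and per-patient-year code counts."""
    if not len(events):
        return CohortSummary(
            followup_years=pd.Series(dtype=int),
            codes_per_year=pd.DataFrame(columns=["patient_id", "year_index",
                                                 "n_codes"]))
    year = (events["age_days"] // DAYS_PER_YEAR).astype(int)
    per_year = (events.assign(year_index=year)
                .groupby(["patient_id", "year_index"], sort=True)
                .size().rename("n_codes").reset_index())
    followup = per_year.groupby("patient_id", sort=True).size()
    followup.name = "followup_years"
    return CohortSummary(followup_years=followup, codes_per_year=per_year)


def write_cohort(out_dir: str | Path, events, demographics, survival,
                 truth: SimTruth, pmap: PhecodeMap) -> dict[str, Path]:
    """Write all cohort artifacts as plain-text files into `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "events.csv",
        "demographics": out / "demographics.csv",
        "survival": out / "survival.csv",
        "truth": out / "truth.json",
        "phecode_map": out / "phecode_map.csv",
    }
    events.to_csv(paths["events"], index=False)
    demographics.to_csv(paths["demographics"], index=False)
    survival.to_csv(paths["survival"], index=False)
    truth.write(paths["truth"])
    pmap.write(paths["phecode_map"])
    return paths
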