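"""Synthetic multimorbidity cohorts with a known generative mechanism.

The generator emulates the structure of a CHARLS-like chronic-disease cohort:
a few thousand patients, 14 disease categories, onset ages 45-90, with
age-increasing co-occurrence driven by shared latent risk factors.  Each
patient carries a nonnegative exposure vector over ``n_factors`` latent
factors (metabolic, vascular, ... in spirit); each disease loads on the
factors.  The yearly onset hazard of disease d for patient p at age a is

    rate = baseline_hazard * base_rate[d] * (1 + loading_scale * x_p · l_d) * g(a)
    P(onset in year a) = 1 - exp(-rate),        g(a) = 1 + (a - age_min)/(age_max - age_min)

With ``loading_scale = 0`` (and ``rate_heterogeneity = 0``) disease onsets
are independent and exchangeable — the calibration null.  A separate step,
:func:`plant_temporal_rule`, makes the "common neighbors predict future
links" premise literally true with controllable strength, recording which
pairs were planted so recovery tests have ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DiseaseCatalog, build_snapshots, CohortTable
from .features import squared_adjacency

Record = tuple[str, int, int]  # (patient_id, disease_id, onset_age)


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the emulated cohort's scale."""

    n_patients: int = 3333
    n_diseases: int = 14
    n_factors: int = 4
    loading_scale: float = 2.0        # coupling of diseases to shared factors
    baseline_hazard: float = 0.0008   # per-year onset rate scale
    rate_heterogeneity: float = 0.6   # lognormal sigma of per-disease base rates
    age_min: int = 45
    age_max: int = 90
    seed: int = 0
    loadings: np.ndarray | None = None  # optional fixed n_diseases×n_factors

    def __post_init__(self):
        if self.n_patients <= 0 or self.n_diseases <= 0 or self.n_factors <= 0:
            raise ValueError("n_patients, n_diseases and n_factors must be positive")
        if self.baseline_hazard <= 0 or self.baseline_hazard >= 1:
            raise ValueError("baseline_hazard must lie in (0, 1)")
        if self.loading_scale < 0 or self.rate_heterogeneity < 0:
            raise ValueError("loading_scale and rate_heterogeneity must be >= 0")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")


@dataclass
class GroundTruth:
    """Everything the generator knew: factors, exposures, realized onsets."""

    loadings: np.ndarray            # n_diseases × n_factors
    exposures: np.ndarray           # n_patients × n_factors
    disease_rates: np.ndarray       # per-disease base-rate multipliers
    records: list[Record]
    planted_pairs: list[tuple[int, int, int]] = field(default_factory=list)  # (age, i, j)

    @property
    def n_multimorbid(self) -> int:
        per_patient: dict[str, set[int]] = {}
        for pid, did, _ in self.records:
            per_patient.setdefault(pid, set()).add(did)
        return sum(1 for dd in per_patient.values() if len(dd) >= 2)


def _age_ramp(ages: np.ndarray, age_min: int, age_max: int) -> np.ndarray:
    return 1.0 + (ages - age_min) / (age_max - age_min)


def simulate_cohort(config: SimConfig) -> tuple[list[Record], GroundTruth]:
    """Draw a cohort; returns raw records (including single-disease patients).

    Filtering to multimorbid patients is deliberately left to
    :func:`cegcn.cohort.load_cohort`, so the fixture path exercises the real
    reader.  Bit-for-bit reproducible for a given config.
    """
    rng = np.random.default_rng(config.seed)
    if config.loadings is not None:
        loadings = np.asarray(config.loadings, dtype=float)
        if loadings.shape != (config.n_diseases, config.n_factors):
            raise ValueError("loadings shape must be (n_diseases, n_factors)")
    else:
        loadings = rng.dirichlet(np.ones(config.n_factors), size=config.n_diseases)
    rates = np.exp(rng.normal(0.0, config.rate_heterogeneity, size=config.n_diseases))
    exposures = rng.gamma(shape=2.0, scale=0.5, size=(config.n_patients, config.n_factors))

    ages = np.arange(config.age_min, config.age_max + 1)
    ramp = _age_ramp(ages, config.age_min, config.age_max)
    # per patient×disease yearly rate modulator
    modulation = 1.0 + config.loading_scale * exposures @ loadings.T  # n_patients × n_diseases
    records: list[Record] = []
    # Draw all Bernoulli years at once for determinism and speed.
    for d in range(config.n_diseases):
        rate = config.baseline_hazard * rates[d] * modulation[:, d:d + 1] * ramp[None, :]
        p_onset = 1.0 - np.exp(-rate)
        draws = rng.random(size=p_onset.shape) < p_onset
        has_onset = draws.any(axis=1)
        first = draws.argmax(axis=1)
        for p in np.nonzero(has_onset)[0]:
            records.append((f"S{p:05d}", d, int(ages[first[p]])))
    records.sort()
    truth = GroundTruth(loadings=loadings, exposures=exposures,
                        disease_rates=rates, records=records)
    return records, truth


def plant_temporal_rule(records: list[Record], config: SimConfig,
                        rule_strength: float, n_boost: int = 2,
                        seed: int | None = None) -> tuple[list[Record], list[tuple[int, int, int]]]:
    """Inject patients so that high-common-neighbor pairs link at the next age.

    Sweeping ages forward, the candidate population at each age is the set
    of not-yet-linked pairs with at least one common neighbor (the pairs a
    link predictor actually ranks).  Pairs in the top quartile of that
    population by common-neighbor count receive ``n_boost`` extra patients
    co-affected at the next age with probability ``min(1, rule_strength)``,
    and are recorded as planted (age-of-appearance, i, j) ground truth.
    Already-linked pairs are left alone: with binary adjacency an extra
    co-affected patient only thickens a weight the model never sees.
    ``rule_strength = 0`` returns the input untouched.
    """
    if rule_strength < 0:
        raise ValueError("rule_strength must be >= 0")
    if rule_strength == 0:
        return list(records), []
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    p_plant = min(1.0, rule_strength)
    augmented = list(records)
    planted: list[tuple[int, int, int]] = []
    n = config.n_diseases
    for age in range(config.age_min, config.age_max):
        # cumulative adjacency at `age` from the augmented record stream
        onsets: dict[str, dict[int, int]] = {}
        for pid, did, a in augmented:
            if a <= age:
                cur = onsets.setdefault(pid, {})
                if did not in cur or a < cur[did]:
                    cur[did] = a
        adj = np.zeros((n, n), dtype=np.int64)
        for dd in onsets.values():
            ds = sorted(dd)
            for ii in range(len(ds)):
                for jj in range(ii + 1, len(ds)):
                    adj[ds[ii], ds[jj]] = adj[ds[jj], ds[ii]] = 1
        common = squared_adjacency(adj)
        iu, ju = np.triu_indices(n, k=1)
        cn_counts = common[iu, ju]
        candidate = (adj[iu, ju] == 0) & (cn_counts > 0)
        n_candidates = int(candidate.sum())
        if n_candidates == 0:
            continue
        n_top = max(1, int(np.ceil(n_candidates / 4)))
        # rank candidates: CN desc, then ascending pair ids (deterministic)
        masked = np.where(candidate, cn_counts, -1)
        order = np.lexsort((iu, ju, -masked))
        for m in order[:n_top]:
            i, j = int(iu[m]), int(ju[m])
            if rng.random() >= p_plant:
                continue
            for b in range(n_boost):
                pid = f"RP{age + 1}_{i}_{j}_{b}"
                augmented.append((pid, i, age + 1))
                augmented.append((pid, j, age + 1))
            planted.append((age + 1, i, j))
    augmented.sort()
    return augmented, planted


def records_to_frame(records: list[Record], catalog: DiseaseCatalog | None = None) -> pd.DataFrame:
    """Long-form DataFrame in the exact dialect ``load_cohort`` reads."""
    df = pd.DataFrame(records, columns=["patient_id", "disease_id", "onset_age"])
    if catalog is not None:
        df["disease"] = [catalog.names[d] for d in df["disease_id"]]
        df = df[["patient_id", "disease", "onset_age"]]
    return df


def write_cohort_csv(records: list[Record], path,
                     catalog: DiseaseCatalog | None = None) -> None:
    records_to_frame(records, catalog).to_csv(path, index=False)


def default_catalog(n_diseases: int = 14) -> DiseaseCatalog:
    """Generic disease catalog for simulations without a named disease list."""
    return DiseaseCatalog(tuple(f"disease_{i:02d}" for i in range(n_diseases)))


def experiment_config(seed: int, n_patients: int = 250,
                      loading_scale: float = 2.0,
                      baseline_hazard: float = 0.0003) -> SimConfig:
    """Reduced-scale study conditions used by the synthetic experiments.

    At 250 patients the hazard is scaled down so the 14-node network
    densifies gradually across the whole 45-90 span instead of saturating by
    mid-age, keeping new-edge targets available in every temporal block.
    """
    return SimConfig(n_patients=n_patients, loading_scale=loading_scale,
                     baseline_hazard=baseline_hazard, seed=seed)


def null_config(seed: int, n_patients: int = 250,
                baseline_hazard: float = 0.001) -> SimConfig:
    """Exchangeable null: no shared factors, no rate spread, no planted rule.

    With ``loading_scale = 0`` *and* ``rate_heterogeneity = 0`` all disease
    pairs are exchangeable, so no ranking signal exists for a leak-free
    model to learn; with rate spread alone, prevalent diseases would still
    co-occur earlier, which is real (if weak) signal.
    """
    return SimConfig(n_patients=n_patients, loading_scale=0.0,
                     rate_heterogeneity=0.0, baseline_hazard=baseline_hazard,
                     seed=seed)


def simulated_sequence(config: SimConfig, rule_strength: float = 0.0,
                       mode: str = "cumulative"):
    """Convenience: simulate, optionally plant the rule, filter, build snapshots.

    Returns (SnapshotSequence, CohortTable, GroundTruth).
    """
    records, truth = simulate_cohort(config)
    if rule_strength > 0:
        records, planted = plant_temporal_rule(records, config, rule_strength)
        truth.planted_pairs = planted
        truth.records = records
    catalog = default_catalog(config.n_diseases)
    # route through the real reader so its filtering applies
    import io
    buf = io.StringIO()
    records_to_frame(records).to_csv(buf, index=False)
    buf.seek(0)
    from .cohort import load_cohort
    cohort = load_cohort(buf, catalog, config.age_min, config.age_max)
    sequence = build_snapshots(cohort, catalog, config.age_min, config.age_max, mode)
    return sequence, cohort, truth
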