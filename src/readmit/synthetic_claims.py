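"""Synthetic administrative-claims generator with known ground truth.

Emulates the statistical structure of an all-payer readmissions database
(hospital-clustered outcomes, extremely skewed diagnosis/procedure code
prevalence, latent disease-cluster co-occurrence, variable-length code
lists, and a readmission process with nonlinear code interactions) so
that every downstream stage — cohort construction, code embedding, the
four risk models, and hospital risk standardization — can be exercised
and validated against a generating truth.

The generator is seeded end to end: identical ``GeneratorConfig`` (which
includes the seed) yields byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.special import expit

__all__ = [
    "CohortProfile",
    "ExclusionRates",
    "GeneratorConfig",
    "CodeUniverse",
    "PROFILES",
    "generate_hospitals",
    "generate_code_universe",
    "generate_admissions",
    "generate_outcomes",
    "generate_dataset",
    "default_config",
    "DEFAULT_BETA0",
    "incidence_matrix",
    "write_claims",
    "read_claims",
]


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


class InputError(ValueError):
    """Raised for invalid inputs to a generator stage."""


@dataclass(frozen=True)
class CohortProfile:
    """Demographic and code-count moments for one index condition.

    Age is in years; ``secondary_dx_mean/sd`` and ``proc_mean/sd`` are the
    moments of the per-admission secondary-diagnosis and procedure code
    counts, modelled as (truncated) negative binomials.
    """

    name: str
    age_mean: float
    age_sd: float
    female_frac: float
    secondary_dx_mean: float
    secondary_dx_sd: float
    proc_mean: float
    proc_sd: float
    readmission_rate: float  # unadjusted target rate, used to set beta0 defaults


#: Condition profiles: acute myocardial infarction, heart failure, pneumonia.
PROFILES: dict[str, CohortProfile] = {
    "ami": CohortProfile("ami", 66.8, 13.7, 0.376, 12.4, 6.1, 5.6, 3.3, 0.120),
    "hf": CohortProfile("hf", 72.5, 14.2, 0.489, 15.1, 5.5, 1.1, 1.9, 0.177),
    "pna": CohortProfile("pna", 69.2, 16.8, 0.518, 12.7, 5.8, 0.7, 1.5, 0.143),
}


@dataclass(frozen=True)
class ExclusionRates:
    """Per-record probabilities of each exclusion condition.

    ``december`` is the probability that the admission month is December
    (no 30-day follow-up window); ``minor_age`` is the probability that the
    record belongs to a patient under 18. ``died``/``ama``/``transfer`` are
    mutually exclusive discharge dispositions.
    """

    died: float = 0.055
    ama: float = 0.012
    transfer: float = 0.034
    zero_los: float = 0.020
    december: float = 1.0 / 12.0
    minor_age: float = 0.003

    def validate(self) -> None:
        vals = (self.died, self.ama, self.transfer, self.zero_los,
                self.december, self.minor_age)
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ConfigError("exclusion rates must lie in [0, 1]")
        if self.died + self.ama + self.transfer > 1.0:
            raise ConfigError("died + ama + transfer must not exceed 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic claims generator.

    Hospital sizes are lognormal; hospital intercepts u_h are
    Normal(0, sigma_hospital^2) on the log-odds scale. Code marginal
    prevalence follows a rank power law (rank^-zipf_exponent) rescaled so
    the most frequent code has prevalence ``max_prevalence``. Each record
    activates 1-2 latent disease clusters and draws its codes with weights
    tilted toward the active clusters, which creates recoverable block
    structure in the record-level co-occurrence matrix.
    """

    n_hospitals: int = 300
    hospital_size_log_mean: float = math.log(130.0)
    hospital_size_log_sd: float = 0.7
    sigma_hospital: float = 0.2
    n_dx_codes: int = 2000
    n_proc_codes: int = 500
    n_clusters: int = 20
    zipf_exponent: float = 1.6
    max_prevalence: float = 0.75
    cohort_profile: str = "ami"
    # outcome model
    beta0: float = -2.63
    beta_age: float = 0.30
    beta_sex: float = 0.15
    code_effect_sd: float = 0.12
    interaction_strength: float = 0.25
    n_interactions: int = 800
    interaction_skip_top: int = 8
    effect_cluster_corr: float = 0.5
    # co-occurrence structure
    cluster_tilt: float = 8.0
    two_cluster_prob: float = 0.5
    # record plumbing
    repeat_patient_frac: float = 0.12
    planned_readmit_frac: float = 0.05
    offcondition_principal_frac: float = 0.02
    n_principal_codes: int = 5
    exclusion_rates: ExclusionRates = field(default_factory=ExclusionRates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_hospitals <= 0:
            raise ConfigError("n_hospitals must be positive")
        if self.n_dx_codes <= 0 or self.n_proc_codes <= 0:
            raise ConfigError("vocabulary sizes must be positive")
        if self.n_clusters <= 0:
            raise ConfigError("n_clusters must be positive")
        if self.n_clusters > self.n_dx_codes:
            raise ConfigError("n_clusters cannot exceed n_dx_codes")
        if self.zipf_exponent <= 0:
            raise ConfigError("zipf_exponent must be positive")
        if not (0.0 < self.max_prevalence <= 1.0):
            raise ConfigError("max_prevalence must lie in (0, 1]")
        if self.cohort_profile not in PROFILES:
            raise ConfigError(f"unknown cohort_profile {self.cohort_profile!r}")
        if self.sigma_hospital < 0 or self.code_effect_sd < 0:
            raise ConfigError("standard deviations must be nonnegative")
        for name in ("repeat_patient_frac", "planned_readmit_frac",
                     "offcondition_principal_frac", "two_cluster_prob",
                     "effect_cluster_corr"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        self.exclusion_rates.validate()

    @property
    def profile(self) -> CohortProfile:
        return PROFILES[self.cohort_profile]

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


#: Baseline log-odds calibrated (once, against the generator's own
#: defaults) so each profile's raw unadjusted readmission rate matches
#: its target: 12.0% AMI, 17.7% HF, 14.3% PNA.
DEFAULT_BETA0 = {"ami": -2.63, "hf": -2.31, "pna": -2.45}


def default_config(profile: str = "ami", **overrides) -> GeneratorConfig:
    """A :class:`GeneratorConfig` with the profile's calibrated baseline."""
    if profile not in PROFILES:
        raise ConfigError(f"unknown cohort_profile {profile!r}")
    kwargs = {"cohort_profile": profile, "beta0": DEFAULT_BETA0[profile]}
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@dataclass
class CodeUniverse:
    """The synthetic ICD-like code universe and its generating truth.

    ``dx_codes``/``proc_codes`` are ordered by decreasing marginal
    prevalence. ``cluster_of`` assigns every code (diagnosis and
    procedure) to exactly one latent disease cluster; interaction triples
    only ever join two same-cluster codes.
    """

    dx_codes: list[str]
    proc_codes: list[str]
    dx_prevalence: np.ndarray
    proc_prevalence: np.ndarray
    dx_cluster: np.ndarray
    proc_cluster: np.ndarray
    dx_effect: np.ndarray
    proc_effect: np.ndarray
    # (code_a, code_b, log-odds) with both codes in the same cluster
    interactions: list[tuple[str, str, float]]
    principal_codes: list[str]

    @property
    def all_codes(self) -> list[str]:
        return self.dx_codes + self.proc_codes

    @property
    def cluster_of(self) -> dict[str, int]:
        out = {c: int(k) for c, k in zip(self.dx_codes, self.dx_cluster)}
        out.update({c: int(k) for c, k in zip(self.proc_codes, self.proc_cluster)})
        return out

    @property
    def marginal_prevalence(self) -> dict[str, float]:
        out = {c: float(p) for c, p in zip(self.dx_codes, self.dx_prevalence)}
        out.update({c: float(p) for c, p in zip(self.proc_codes, self.proc_prevalence)})
        return out

    @property
    def true_effect(self) -> dict[str, float]:
        out = {c: float(e) for c, e in zip(self.dx_codes, self.dx_effect)}
        out.update({c: float(e) for c, e in zip(self.proc_codes, self.proc_effect)})
        return out


def _spawn(seed: int, *path: int) -> np.random.Generator:
    """Independent child stream for a generator stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=path))


def generate_hospitals(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the hospital frame: id, admission volume, true intercept u.

    Sizes are lognormal rounded to at least one admission; intercepts are
    i.i.d. Normal(0, sigma_hospital^2) on the log-odds scale.
    """
    config.validate()
    rng = _spawn(config.seed, 0)
    sizes = np.maximum(
        1,
        np.round(rng.lognormal(config.hospital_size_log_mean,
                               config.hospital_size_log_sd,
                               config.n_hospitals)).astype(np.int64),
    )
    u = rng.normal(0.0, config.sigma_hospital, config.n_hospitals)
    if config.sigma_hospital == 0:
        u = np.zeros(config.n_hospitals)
    return pd.DataFrame({
        "hospital_id": np.arange(config.n_hospitals, dtype=np.int64),
        "n_admissions": sizes,
        "u": u,
    })


def _sample_tilted_codes(rng: np.random.Generator, prev: np.ndarray,
                         cluster: np.ndarray, counts: np.ndarray,
                         c1: np.ndarray, c2: np.ndarray, tilt: float,
                         K: int, extra: int = 0) -> list[np.ndarray]:
    """Cluster-tilted weighted sampling without replacement, per record.

    Record i draws ``counts[i] + extra`` distinct codes sequentially with
    probability proportional to prevalence, multiplied by ``tilt`` for
    codes in the record's active clusters (c1[i], c2[i]). Returned index
    arrays are in draw order.
    """
    n = counts.shape[0]
    logp = np.log(prev)
    logt = math.log(tilt) if tilt > 0 else 0.0
    V = prev.shape[0]
    draw = np.minimum(counts + extra, V)
    key = np.minimum(c1, c2) * K + np.maximum(c1, c2)
    out: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    for k in np.unique(key):
        mask = key == k
        ka, kb = divmod(int(k), K)
        logw = logp + logt * ((cluster == ka) | (cluster == kb))
        idx_rows = np.flatnonzero(mask)
        sub = _gumbel_topk(rng, logw, draw[idx_rows],
                           int(draw[idx_rows].max(initial=0)))
        for r, s in zip(idx_rows, sub):
            out[r] = s
    return out


def _inclusion_probability(prev: np.ndarray, cluster: np.ndarray,
                           config: "GeneratorConfig", count_mean: float,
                           count_sd: float, cap: int,
                           rng: np.random.Generator,
                           n_sim: int = 4000) -> np.ndarray:
    """Monte-Carlo estimate of each code's record-inclusion probability.

    Used only to center the per-code effects so beta0 identifies the
    baseline readmission rate: simulates ``n_sim`` records under exactly
    the sampling law of :func:`generate_admissions` and counts how often
    each code appears.
    """
    K = config.n_clusters
    counts = _sample_counts(rng, count_mean, count_sd, n_sim, cap)
    c1 = rng.integers(0, K, n_sim)
    c2 = rng.integers(0, K, n_sim)
    has2 = rng.random(n_sim) < config.two_cluster_prob
    c2 = np.where(has2, c2, c1)
    idx = _sample_tilted_codes(rng, prev, cluster, counts, c1, c2,
                               config.cluster_tilt, K)
    freq = np.zeros(prev.shape[0])
    for s in idx:
        freq[s] += 1.0
    return np.clip(freq / n_sim, 1e-6, 1.0)


def _power_law(n: int, exponent: float, top: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    p = ranks ** (-exponent)
    return top * p / p[0]


def generate_code_universe(config: GeneratorConfig) -> CodeUniverse:
    """Build the code universe: prevalences, clusters, effects, interactions.

    Marginal prevalence is proportional to rank^-zipf_exponent, rescaled so
    the top code reaches ``max_prevalence``. Codes are dealt round-robin
    into clusters so every cluster owns both frequent and rare codes.
    Interaction triples join two distinct same-cluster codes, preferring
    prevalent codes (weighted by prevalence) so that interactions actually
    co-occur in records; each has log-odds ``interaction_strength``.
    """
    config.validate()
    rng = _spawn(config.seed, 1)
    n_dx, n_proc, K = config.n_dx_codes, config.n_proc_codes, config.n_clusters

    dx_codes = [f"D{i:04d}" for i in range(n_dx)]
    proc_codes = [f"P{i:04d}" for i in range(n_proc)]
    dx_prev = _power_law(n_dx, config.zipf_exponent, config.max_prevalence)
    proc_prev = _power_law(n_proc, config.zipf_exponent, config.max_prevalence)

    dx_cluster = np.arange(n_dx, dtype=np.int64) % K
    proc_cluster = np.arange(n_proc, dtype=np.int64) % K

    # per-code effects: marginally Normal(0, code_effect_sd^2), with a
    # within-cluster correlated component (clinically similar codes carry
    # similar risk — the structure code embeddings can exploit)
    rho = config.effect_cluster_corr
    cluster_mean = rng.normal(0.0, 1.0, K)
    dx_effect = config.code_effect_sd * (
        np.sqrt(rho) * cluster_mean[dx_cluster]
        + np.sqrt(1.0 - rho) * rng.normal(0.0, 1.0, n_dx))
    proc_effect = config.code_effect_sd * (
        np.sqrt(rho) * cluster_mean[proc_cluster]
        + np.sqrt(1.0 - rho) * rng.normal(0.0, 1.0, n_proc))
    if config.code_effect_sd == 0:
        dx_effect = np.zeros(n_dx)
        proc_effect = np.zeros(n_proc)
    else:
        # center effects by Monte-Carlo record-inclusion probability, so
        # the baseline readmission rate stays identified by beta0 rather
        # than by the luck of which high-prevalence codes drew large
        # effects
        prof = config.profile
        dx_effect -= np.average(
            dx_effect, weights=_inclusion_probability(
                dx_prev, dx_cluster, config, prof.secondary_dx_mean,
                prof.secondary_dx_sd, 29, rng))
        proc_effect -= np.average(
            proc_effect, weights=_inclusion_probability(
                proc_prev, proc_cluster, config, prof.proc_mean,
                prof.proc_sd, 15, rng))

    interactions: list[tuple[str, str, float]] = []
    if config.interaction_strength != 0.0 and config.n_interactions > 0:
        seen: set[tuple[int, int]] = set()
        # sample within-cluster diagnosis pairs, prevalence-weighted but
        # excluding the near-ubiquitous top codes: a pair whose one member
        # is present in ~every record degenerates to a main effect of the
        # other member, which any linear model absorbs — genuine
        # combinatorial signal needs both members at middling prevalence
        skip_top = min(config.interaction_skip_top, n_dx)
        members = [np.flatnonzero(dx_cluster[skip_top:] == k) + skip_top
                   for k in range(K)]
        tries = 0
        while len(interactions) < config.n_interactions and tries < 50 * config.n_interactions:
            tries += 1
            k = int(rng.integers(K))
            m = members[k]
            if m.size < 2:
                continue
            w = dx_prev[m] / dx_prev[m].sum()
            a, b = rng.choice(m, size=2, replace=False, p=w)
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            interactions.append((dx_codes[key[0]], dx_codes[key[1]],
                                 float(config.interaction_strength)))

    # principal codes: dedicated mid-prevalence diagnosis codes for the
    # condition; kept out of the interaction machinery by construction
    lo = min(15, n_dx - config.n_principal_codes)
    principal = dx_codes[lo:lo + config.n_principal_codes]

    return CodeUniverse(dx_codes, proc_codes, dx_prev, proc_prev,
                        dx_cluster, proc_cluster, dx_effect, proc_effect,
                        interactions, principal)


def _sample_counts(rng: np.random.Generator, mean: float, sd: float,
                   n: int, cap: int) -> np.ndarray:
    """Negative-binomial counts matched to (mean, sd), truncated at cap.

    Falls back to Poisson when the target variance does not exceed the
    mean (the NB limit).
    """
    var = sd * sd
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    if var > mean:
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        draws = rng.negative_binomial(r, p, n)
    else:
        draws = rng.poisson(mean, n)
    return np.minimum(draws, cap).astype(np.int64)


def _gumbel_topk(rng: np.random.Generator, logw: np.ndarray,
                 counts: np.ndarray, max_k: int,
                 chunk: int = 2048) -> list[np.ndarray]:
    """Weighted sampling without replacement via the Gumbel-top-k trick.

    For each row i, returns ``counts[i]`` distinct column indices drawn
    sequentially proportional to exp(logw) — identical in law to
    successive draws without replacement.
    """
    n = counts.shape[0]
    out: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    if max_k == 0:
        return [np.empty(0, dtype=np.int64) for _ in range(n)]
    V = logw.shape[0]
    kk = min(max_k, V)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        m = stop - start
        g = rng.gumbel(size=(m, V))
        g += logw[None, :]
        part = np.argpartition(-g, kk - 1, axis=1)[:, :kk]
        vals = np.take_along_axis(g, part, axis=1)
        order = np.argsort(-vals, axis=1)
        top = np.take_along_axis(part, order, axis=1)
        for i in range(m):
            c = counts[start + i]
            # kept in score order = sequential-draw order
            out[start + i] = top[i, :c].astype(np.int64)
    return out


def generate_admissions(config: GeneratorConfig, hospitals: pd.DataFrame,
                        universe: CodeUniverse) -> pd.DataFrame:
    """Generate the raw admission table (without outcomes).

    One row per admission. Repeat patients (a configurable fraction) get
    2-4 admissions within the same hospital so first-admission selection
    has work to do. Codes are drawn without replacement from the
    cluster-tilted prevalence law: each record activates one latent
    cluster (or two, with probability ``two_cluster_prob``) and code
    weights are multiplied by ``cluster_tilt`` inside active clusters.
    """
    config.validate()
    if hospitals is None or len(hospitals) == 0:
        raise InputError("empty hospital table")
    rng = _spawn(config.seed, 2)
    prof = config.profile
    ex = config.exclusion_rates
    K = config.n_clusters

    sizes = hospitals["n_admissions"].to_numpy()
    n = int(sizes.sum())
    hosp_ids = np.repeat(hospitals["hospital_id"].to_numpy(), sizes)

    # --- patients: some patients own 2-4 admissions within a hospital
    patient_id = np.empty(n, dtype=np.int64)
    next_pid = 0
    pos = 0
    for sz in sizes:
        remaining = int(sz)
        while remaining > 0:
            if remaining >= 2 and rng.random() < config.repeat_patient_frac:
                k = int(rng.integers(2, 5))
                k = min(k, remaining)
            else:
                k = 1
            patient_id[pos:pos + k] = next_pid
            next_pid += 1
            pos += k
            remaining -= k

    # --- demographics: adult ages truncated at 18; minors only through
    # the configured rate, so the age<18 exclusion is fully controllable
    age = rng.normal(prof.age_mean, prof.age_sd, n)
    age = np.clip(age, 18.0, None)
    minors = rng.random(n) < ex.minor_age
    age[minors] = rng.uniform(1.0, 17.5, int(minors.sum()))
    female = (rng.random(n) < prof.female_frac).astype(np.int8)

    # --- admission month: December with its own rate, else uniform Jan-Nov;
    # repeat admissions of one patient get months sorted ascending
    month = np.where(rng.random(n) < ex.december, 12,
                     rng.integers(1, 12, n)).astype(np.int8)
    order = np.argsort(patient_id, kind="stable")
    srt = month[order]
    bounds = np.flatnonzero(np.diff(patient_id[order])) + 1
    for a, b in zip(np.concatenate(([0], bounds)),
                    np.concatenate((bounds, [n]))):
        if b - a > 1:
            srt[a:b] = np.sort(srt[a:b])
    month[order] = srt

    # --- discharge disposition (mutually exclusive) and length of stay
    disp = rng.random(n)
    died = (disp < ex.died).astype(np.int8)
    ama = ((disp >= ex.died) & (disp < ex.died + ex.ama)).astype(np.int8)
    transfer = ((disp >= ex.died + ex.ama)
                & (disp < ex.died + ex.ama + ex.transfer)).astype(np.int8)
    los = 1 + rng.poisson(4.0, n)
    los[rng.random(n) < ex.zero_los] = 0

    # --- latent active clusters per record
    c1 = rng.integers(0, K, n)
    c2 = rng.integers(0, K, n)
    has2 = rng.random(n) < config.two_cluster_prob
    c2 = np.where(has2, c2, c1)

    # --- principal diagnosis
    prin_pool = np.array([universe.dx_codes.index(c) for c in universe.principal_codes])
    prin_idx = rng.choice(prin_pool, size=n)
    off = rng.random(n) < config.offcondition_principal_frac
    if off.any():
        w = universe.dx_prevalence.copy()
        w[prin_pool] = 0.0
        w /= w.sum()
        prin_idx[off] = rng.choice(config.n_dx_codes, size=int(off.sum()), p=w)

    # --- secondary diagnosis and procedure codes, cluster-tilted
    n_sec = _sample_counts(rng, prof.secondary_dx_mean, prof.secondary_dx_sd, n, 29)
    n_proc = _sample_counts(rng, prof.proc_mean, prof.proc_sd, n, 15)

    dx_codes_arr = np.asarray(universe.dx_codes, dtype=object)
    proc_codes_arr = np.asarray(universe.proc_codes, dtype=object)

    # one spare candidate: if the record's principal code comes up among
    # the secondary draws it is skipped, keeping the count law intact
    sec_idx = _sample_tilted_codes(rng, universe.dx_prevalence,
                                   universe.dx_cluster, n_sec, c1, c2,
                                   config.cluster_tilt, K, extra=1)
    proc_idx = _sample_tilted_codes(rng, universe.proc_prevalence,
                                    universe.proc_cluster, n_proc, c1, c2,
                                    config.cluster_tilt, K)

    secondary = []
    for i, s in enumerate(sec_idx):
        s = s[s != prin_idx[i]][:n_sec[i]]
        secondary.append(list(dx_codes_arr[s]))
    procedures = [list(proc_codes_arr[s]) for s in proc_idx]
    principal = list(dx_codes_arr[prin_idx])

    return pd.DataFrame({
        "patient_id": patient_id,
        "hospital_id": hosp_ids,
        "age": age,
        "female": female,
        "admission_month": month,
        "length_of_stay": los.astype(np.int16),
        "died": died,
        "ama": ama,
        "transfer_out": transfer,
        "principal_dx": principal,
        "secondary_dx": secondary,
        "procedures": procedures,
    })


def incidence_matrix(records: pd.DataFrame, codes: list[str],
                     include_principal: bool = True,
                     include_secondary: bool = True,
                     include_procedures: bool = True) -> csr_matrix:
    """Binary record x code incidence matrix over the given vocabulary.

    Presence-based: a code appearing in a record contributes a single 1
    regardless of which list it sits in.
    """
    index = {c: j for j, c in enumerate(codes)}
    rows: list[int] = []
    cols: list[int] = []
    for i, (prin, sec, proc) in enumerate(zip(records["principal_dx"],
                                              records["secondary_dx"],
                                              records["procedures"])):
        seen: set[int] = set()
        if include_principal:
            j = index.get(prin)
            if j is not None:
                seen.add(j)
        if include_secondary:
            for c in sec:
                j = index.get(c)
                if j is not None:
                    seen.add(j)
        if include_procedures:
            for c in proc:
                j = index.get(c)
                if j is not None:
                    seen.add(j)
        rows.extend([i] * len(seen))
        cols.extend(seen)
    data = np.ones(len(rows), dtype=np.int8)
    return csr_matrix((data, (rows, cols)),
                      shape=(len(records), len(codes)))


def generate_outcomes(table: pd.DataFrame, hospitals: pd.DataFrame,
                      universe: CodeUniverse,
                      config: GeneratorConfig) -> pd.DataFrame:
    """Attach the readmission-generating truth and sampled labels.

    logit(true_p) = beta0 + beta_age * z(age) + beta_sex * female
                    + sum of per-code effects over all codes present
                    + sum of within-cluster pairwise interaction effects
                    + u_hospital.
    Age is z-scored against the profile mean/SD. ``readmit_30d`` is a
    Bernoulli(true_p) draw; a small fraction of readmissions is flagged
    planned.
    """
    config.validate()
    if not set(table["hospital_id"]).issubset(set(hospitals["hospital_id"])):
        raise InputError("records reference hospitals without intercepts")
    rng = _spawn(config.seed, 3)
    prof = config.profile

    u_map = hospitals.set_index("hospital_id")["u"]
    u = u_map.loc[table["hospital_id"]].to_numpy()

    z_age = (table["age"].to_numpy() - prof.age_mean) / prof.age_sd
    eta = (config.beta0
           + config.beta_age * z_age
           + config.beta_sex * table["female"].to_numpy()
           + u)

    all_codes = universe.all_codes
    M = incidence_matrix(table, all_codes)
    effects = np.concatenate([universe.dx_effect, universe.proc_effect])
    eta = eta + M @ effects

    if universe.interactions:
        pos = {c: j for j, c in enumerate(all_codes)}
        ia = np.array([pos[a] for a, _, _ in universe.interactions])
        ib = np.array([pos[b] for _, b, _ in universe.interactions])
        gamma = np.array([g for _, _, g in universe.interactions])
        Mc = M.tocsc()
        both = Mc[:, ia].multiply(Mc[:, ib])
        eta = eta + both @ gamma

    true_p = expit(eta)
    label = (rng.random(len(table)) < true_p).astype(np.int8)
    planned = np.zeros(len(table), dtype=np.int8)
    readmits = np.flatnonzero(label == 1)
    planned[readmits[rng.random(readmits.size) < config.planned_readmit_frac]] = 1

    out = table.copy()
    out["readmit_30d"] = label
    out["planned_readmit"] = planned
    out["true_p"] = true_p
    return out


def generate_dataset(config: GeneratorConfig):
    """Run the full generator pipeline; returns (hospitals, universe, table)."""
    hospitals = generate_hospitals(config)
    universe = generate_code_universe(config)
    table = generate_admissions(config, hospitals, universe)
    table = generate_outcomes(table, hospitals, universe, config)
    return hospitals, universe, table


# ---------------------------------------------------------------------------
# on-disk claims schema


def _join(codes: list[str]) -> str:
    return " ".join(codes)


def _split(s) -> list[str]:
    if isinstance(s, float) or s is None or s == "":
        return []
    return str(s).split(" ")


def write_claims(table: pd.DataFrame, path, fmt: str = "csv") -> None:
    """Write the claims table (CSV or parquet).

    Ground-truth columns (``true_p``) are written to a ``.truth`` sidecar
    so model code cannot accidentally consume them.
    """
    flat = table.copy()
    flat["secondary_dx"] = [_join(c) for c in flat["secondary_dx"]]
    flat["procedures"] = [_join(c) for c in flat["procedures"]]
    truth_cols = [c for c in ("true_p",) if c in flat.columns]
    truth = flat[truth_cols]
    flat = flat.drop(columns=truth_cols)
    path = str(path)
    if fmt == "csv":
        flat.to_csv(path, index=False)
        if truth_cols:
            truth.to_csv(path + ".truth", index=False)
    elif fmt == "parquet":
        flat.to_parquet(path, index=False)
        if truth_cols:
            truth.to_parquet(path + ".truth", index=False)
    else:
        raise ConfigError(f"unknown claims format {fmt!r}")


def read_claims(path, fmt: str = "csv") -> pd.DataFrame:
    """Read a claims table written by :func:`write_claims` (no truth columns)."""
    path = str(path)
    if fmt == "csv":
        flat = pd.read_csv(path, keep_default_na=False)
    elif fmt == "parquet":
        flat = pd.read_parquet(path)
    else:
        raise ConfigError(f"unknown claims format {fmt!r}")
    flat["secondary_dx"] = [_split(s) for s in flat["secondary_dx"]]
    flat["procedures"] = [_split(s) for s in flat["procedures"]]
    return flat
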