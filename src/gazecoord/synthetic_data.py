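"""Synthetic dyadic gaze corpora with the statistical structure the analyses assume.

The generator emulates a table-top instruction task: in every
reference-action sequence an *instructor* verbally refers to one ingredient
(the referent) and a *worker* moves it to a target bread.  Each sequence has
five contiguous phases with gamma-distributed durations; each participant's
gaze is a renewal process of fixations (lognormal dwells) over five targets
-- the referent, some other ingredient, the target bread, the partner, or
unmapped gaze that hits no AOI.

Coordination enters through three mechanisms:

* **Coupling.**  At each of its fixation onsets ``t`` the worker, with
  per-phase probability ``rho``, adopts whatever the instructor is gazing at
  at ``t - lead`` (per-phase lead in ms; positive = instructor leads,
  negative = the worker runs ahead) and holds it for as long as the
  instructor holds it.  Otherwise the worker samples from its own per-phase
  marginal.
* **Referential timing.**  The instructor first fixates the referent a
  configured interval before the verbal reference onset (and keeps
  returning to it); the worker's first referent fixation happens a
  configured latency after the onset.  Before those moments referent
  fixations are suppressed (redrawn), after them gaze is free.
* **Repair perturbations.**  Sequences flagged as containing a
  conversational repair perturb the worker's per-phase marginals (more
  gaze to non-referents during and after the reference, more target-bread
  gaze before it), emulating the breakdown signature.

Everything is driven by one seeded :class:`numpy.random.Generator`;
regeneration from the same seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .gaze_model import (
    CATEGORIES,
    PHASES,
    PARTNER,
    TARGET_BREAD,
    UNMAPPED,
    ValidationError,
    validate_fixations,
    validate_sequences,
    write_fixations,
    write_sequences,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticCorpus",
    "default_config",
    "generate",
    "expected_alignment",
    "expected_same_target",
]

# category indices inside the generator: 0..3 as in CATEGORIES, 4 = unmapped
_N_CAT = 5
_REF, _OTH, _TGT, _PER, _UNM = range(_N_CAT)
_CAT_KEYS = ("reference", "other", "target", "person", "unmapped")


def _dist_array(d: Dict[str, float]) -> np.ndarray:
    return np.array([float(d.get(k, 0.0)) for k in _CAT_KEYS], dtype=float)


def _lognorm_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and coefficient of variation."""
    sigma2 = math.log(1.0 + cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic dyad-gaze generator.

    Distributions are per phase over ``(reference, other, target, person,
    unmapped)`` and must lie on the simplex.  ``lead_ms`` is the per-phase
    gaze lead (positive = instructor leads the worker); ``coupling_rho`` the
    per-phase probability that a worker fixation copies the instructor.
    Durations and leads/latencies are in seconds, dwells in milliseconds.
    """

    phase_duration_mean_s: Dict[str, float]
    phase_duration_cv: float
    instructor_dist: Dict[str, Dict[str, float]]
    worker_dist: Dict[str, Dict[str, float]]
    coupling_rho: Dict[str, float]
    lead_ms: Dict[str, int]
    dwell_mean_ms: float
    dwell_cv: float
    min_dwell_ms: int
    instructor_ref_lead_mean_s: float
    instructor_ref_lead_cv: float
    worker_ref_latency_mean_s: float
    worker_ref_latency_cv: float
    repair_prob: float
    repair_worker_deltas: Dict[str, Dict[str, float]]
    n_ingredients: int = 23
    inter_sequence_gap_ms: int = 400
    segment_ms: int = 50

    def __post_init__(self):
        for phase in PHASES:
            if self.phase_duration_mean_s[phase] <= 0:
                raise ValidationError(f"non-positive duration mean for phase {phase}")
            rho = self.coupling_rho[phase]
            if not 0.0 <= rho <= 1.0:
                raise ValidationError(f"coupling_rho out of [0,1] for phase {phase}")
            for name, dists in (("instructor", self.instructor_dist), ("worker", self.worker_dist)):
                p = _dist_array(dists[phase])
                if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                    raise ValidationError(f"{name} distribution for phase {phase} is not on the simplex")
            p = self.perturbed_worker_dist(phase)
            if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"repair perturbation leaves the simplex for phase {phase}"
                )

    def instructor_p(self, phase: str) -> np.ndarray:
        return _dist_array(self.instructor_dist[phase])

    def worker_p(self, phase: str, repair: bool = False) -> np.ndarray:
        if repair:
            return self.perturbed_worker_dist(phase)
        return _dist_array(self.worker_dist[phase])

    def perturbed_worker_dist(self, phase: str) -> np.ndarray:
        p = _dist_array(self.worker_dist[phase])
        delta = self.repair_worker_deltas.get(phase, {})
        for k, v in delta.items():
            p[_CAT_KEYS.index(k)] += float(v)
        return p

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config() -> GeneratorConfig:
    """The packaged default configuration (see ``defaults.yaml``)."""
    return GeneratorConfig.from_yaml(Path(__file__).parent / "defaults.yaml")


@dataclass
class SyntheticCorpus:
    fixations: pd.DataFrame
    sequences: pd.DataFrame
    config: GeneratorConfig
    seed: int

    def write(self, directory, prefix: str = "corpus") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fixations(self.fixations, directory / f"{prefix}_fixations.tsv")
        write_sequences(self.sequences, directory / f"{prefix}_sequences.tsv")
        self.config.to_yaml(directory / f"{prefix}_config.yaml")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

class _Draws:
    """Buffered scalar draws from one Generator (keeps the hot loop cheap)."""

    def __init__(self, rng: np.random.Generator, block: int = 256):
        self.rng = rng
        self.block = block
        self._u = np.empty(0)
        self._z = np.empty(0)
        self._iu = self._iz = 0

    def u(self) -> float:
        if self._iu >= self._u.size:
            self._u = self.rng.random(self.block)
            self._iu = 0
        v = self._u[self._iu]
        self._iu += 1
        return v

    def z(self) -> float:
        if self._iz >= self._z.size:
            self._z = self.rng.standard_normal(self.block)
            self._iz = 0
        v = self._z[self._iz]
        self._iz += 1
        return v


def _phase_of(t: int, edges: np.ndarray) -> int:
    # edges has 6 entries; t assumed within [edges[0], edges[5])
    p = 0
    while p < 4 and t >= edges[p + 1]:
        p += 1
    return p


def _gen_instructor(
    draws: _Draws,
    cfg: GeneratorConfig,
    edges: np.ndarray,
    onset: int,
    forced_t: int,
    referent: int,
    cum: np.ndarray,
    cum_no_ref: np.ndarray,
    mu_d: float,
    sg_d: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Instructor fixation stream for one sequence (times relative to 0).

    Referent fixations are suppressed before ``forced_t`` (= reference onset
    minus the drawn anticipatory lead); a referent fixation is forced there.
    Returns (t0, t1, cat, aoi) arrays; ``aoi`` is an ingredient index, or
    -1 target bread / -2 partner / -3 unmapped.
    """
    seq_end = int(edges[-1])
    t0s, t1s, cats, aois = [], [], [], []
    t = 0
    forced_pending = forced_t < seq_end

    def dwell() -> int:
        return max(cfg.min_dwell_ms, int(round(math.exp(mu_d + sg_d * draws.z()))))

    def draw_cat(phase: int, allow_ref: bool) -> int:
        c = cum[phase] if allow_ref else cum_no_ref[phase]
        u = draws.u()
        k = 0
        while c[k] < u:
            k += 1
        return k

    def draw_aoi(cat: int) -> int:
        if cat == _REF:
            return referent
        if cat == _OTH:
            k = int(draws.u() * (cfg.n_ingredients - 1))
            return k if k < referent else k + 1
        return {_TGT: -1, _PER: -2, _UNM: -3}[cat]

    while t < seq_end:
        if forced_pending and t >= forced_t:
            d = dwell()
            t0s.append(t)
            t1s.append(min(t + d, seq_end))
            cats.append(_REF)
            aois.append(referent)
            t = min(t + d, seq_end)
            forced_pending = False
            continue
        phase = _phase_of(t, edges)
        allow_ref = not (forced_pending and t < forced_t)
        cat = draw_cat(phase, allow_ref)
        d = dwell()
        end = t + d
        if forced_pending and end > forced_t:
            end = forced_t  # truncate at the forced referent fixation
        end = min(end, seq_end)
        if end > t:
            t0s.append(t)
            t1s.append(end)
            cats.append(cat)
            aois.append(draw_aoi(cat))
        t = end if end > t else t + 1
    return (
        np.array(t0s, dtype=np.int64),
        np.array(t1s, dtype=np.int64),
        np.array(cats, dtype=np.int8),
        np.array(aois, dtype=np.int64),
    )


def _gen_worker(
    draws: _Draws,
    cfg: GeneratorConfig,
    edges: np.ndarray,
    onset: int,
    forced_t: int,
    referent: int,
    instr: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    cum: np.ndarray,
    cum_no_ref: np.ndarray,
    rho: np.ndarray,
    lead: np.ndarray,
    mu_d: float,
    sg_d: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Worker stream: coupled copies of the (lead-shifted) instructor gaze
    mixed with marginal draws; referent gaze suppressed before ``forced_t``
    (= reference onset + the drawn latency), where a referent fixation is
    forced."""
    seq_end = int(edges[-1])
    i_t0, i_t1, i_cat, i_aoi = instr
    t0s, t1s, cats, aois = [], [], [], []
    t = 0
    forced_pending = forced_t < seq_end

    def dwell() -> int:
        return max(cfg.min_dwell_ms, int(round(math.exp(mu_d + sg_d * draws.z()))))

    def draw_cat(phase: int, allow_ref: bool) -> int:
        c = cum[phase] if allow_ref else cum_no_ref[phase]
        u = draws.u()
        k = 0
        while c[k] < u:
            k += 1
        return k

    def draw_aoi(cat: int) -> int:
        if cat == _REF:
            return referent
        if cat == _OTH:
            k = int(draws.u() * (cfg.n_ingredients - 1))
            return k if k < referent else k + 1
        return {_TGT: -1, _PER: -2, _UNM: -3}[cat]

    while t < seq_end:
        if forced_pending and t >= forced_t:
            d = dwell()
            t0s.append(t)
            t1s.append(min(t + d, seq_end))
            cats.append(_REF)
            aois.append(referent)
            t = min(t + d, seq_end)
            forced_pending = False
            continue
        phase = _phase_of(t, edges)
        suppressed = forced_pending and t < forced_t
        cat = -1
        if draws.u() < rho[phase]:
            src = t - lead[phase]
            if 0 <= src < seq_end and i_t0.size:
                k = int(np.searchsorted(i_t0, src, side="right")) - 1
                if k >= 0 and src < i_t1[k]:
                    c = int(i_cat[k])
                    # partner-directed gaze cannot be followed (the target is
                    # the follower); suppressed referent copies also fall back
                    if c != _PER and not (c == _REF and suppressed):
                        cat = c
                        aoi = int(i_aoi[k])
                        d = max(cfg.min_dwell_ms, int(i_t1[k] - src))
        if cat < 0:  # marginal draw (uncoupled, source invalid, or suppressed copy)
            cat = draw_cat(phase, not suppressed)
            aoi = draw_aoi(cat)
            d = dwell()
        end = t + d
        if forced_pending and end > forced_t:
            end = forced_t
        end = min(end, seq_end)
        if end > t:
            t0s.append(t)
            t1s.append(end)
            cats.append(cat)
            aois.append(aoi)
        t = end if end > t else t + 1
    return (
        np.array(t0s, dtype=np.int64),
        np.array(t1s, dtype=np.int64),
        np.array(cats, dtype=np.int8),
        np.array(aois, dtype=np.int64),
    )


def _aoi_label(aoi: int) -> str:
    if aoi == -1:
        return TARGET_BREAD
    if aoi == -2:
        return PARTNER
    if aoi == -3:
        return UNMAPPED
    return f"ing{aoi:02d}"


def generate(
    config: GeneratorConfig,
    n_dyads: int = 13,
    n_interactions: int = 2,
    n_sequences: int = 15,
    seed: int = 0,
    validate: bool = False,
) -> SyntheticCorpus:
    """Generate a corpus of ``n_dyads x n_interactions x n_sequences``
    reference-action sequences.

    Phase durations are gamma draws with the configured mean and CV; the
    instructor stream is generated first and the worker stream coupled to it
    (see the module docstring for the coupling and timing mechanisms).
    Repair flags are i.i.d. Bernoulli(``repair_prob``) per sequence.
    """
    if n_dyads < 1 or n_sequences < 1:
        raise ValueError("need at least one dyad and one sequence")
    rng = np.random.default_rng(seed)
    draws = _Draws(rng)
    cfg = config

    cum_i = np.vstack([np.cumsum(cfg.instructor_p(p)) for p in PHASES])
    cum_w = {
        rep: np.vstack([np.cumsum(cfg.worker_p(p, rep)) for p in PHASES])
        for rep in (False, True)
    }

    def _no_ref(cum_rows: np.ndarray) -> np.ndarray:
        out = np.empty_like(cum_rows)
        for r in range(cum_rows.shape[0]):
            p = np.diff(np.concatenate([[0.0], cum_rows[r]]))
            p[_REF] = 0.0
            s = p.sum()
            out[r] = np.cumsum(p / s if s > 0 else np.full(_N_CAT, 1.0 / _N_CAT))
        return out

    cum_i_nr = _no_ref(cum_i)
    cum_w_nr = {rep: _no_ref(cum_w[rep]) for rep in (False, True)}

    rho = np.array([cfg.coupling_rho[p] for p in PHASES])
    lead = np.array([int(cfg.lead_ms[p]) for p in PHASES], dtype=np.int64)
    mu_d, sg_d = _lognorm_params(cfg.dwell_mean_ms, cfg.dwell_cv)
    timing_i = cfg.instructor_ref_lead_mean_s > 0
    timing_w = cfg.worker_ref_latency_mean_s > 0
    if timing_i:
        mu_il, sg_il = _lognorm_params(cfg.instructor_ref_lead_mean_s, cfg.instructor_ref_lead_cv)
    if timing_w:
        mu_wl, sg_wl = _lognorm_params(cfg.worker_ref_latency_mean_s, cfg.worker_ref_latency_cv)
    k_gamma = 1.0 / (cfg.phase_duration_cv**2)
    means = np.array([cfg.phase_duration_mean_s[p] for p in PHASES])

    fix_rows = {k: [] for k in ("dyad_id", "interaction_id", "role", "t_start_ms", "t_end_ms", "aoi_raw")}
    seq_rows = []

    for dy in range(n_dyads):
        dyad_id = f"d{dy:02d}"
        for inter in range(1, n_interactions + 1):
            t_cursor = 0
            for s in range(n_sequences):
                durs_ms = np.maximum(
                    cfg.segment_ms,
                    np.round(rng.gamma(k_gamma, means * cfg.phase_duration_cv**2 / 1.0) * 1000).astype(np.int64),
                )
                edges = np.concatenate([[0], np.cumsum(durs_ms)])
                onset = int(edges[1])  # reference onset = start of reference phase
                seq_end = int(edges[-1])
                referent = int(rng.integers(cfg.n_ingredients))
                repair = bool(rng.random() < cfg.repair_prob)

                if timing_i:
                    lead_i_ms = int(round(math.exp(mu_il + sg_il * draws.z()) * 1000))
                    lead_i_ms = min(max(lead_i_ms, cfg.min_dwell_ms), onset)
                    forced_i = onset - lead_i_ms
                else:
                    forced_i = 1 << 62  # referential timing disabled
                if timing_w:
                    lat_w_ms = max(
                        cfg.min_dwell_ms, int(round(math.exp(mu_wl + sg_wl * draws.z()) * 1000))
                    )
                    forced_w = onset + lat_w_ms
                else:
                    forced_w = 1 << 62

                instr = _gen_instructor(
                    draws, cfg, edges, onset, forced_i, referent, cum_i, cum_i_nr, mu_d, sg_d
                )
                work = _gen_worker(
                    draws,
                    cfg,
                    edges,
                    onset,
                    forced_w,
                    referent,
                    instr,
                    cum_w[repair],
                    cum_w_nr[repair],
                    rho,
                    lead,
                    mu_d,
                    sg_d,
                )
                for role, (t0, t1, cat, aoi) in (("instructor", instr), ("worker", work)):
                    n = t0.size
                    fix_rows["dyad_id"].extend([dyad_id] * n)
                    fix_rows["interaction_id"].extend([inter] * n)
                    fix_rows["role"].extend([role] * n)
                    fix_rows["t_start_ms"].extend((t0 + t_cursor).tolist())
                    fix_rows["t_end_ms"].extend((t1 + t_cursor).tolist())
                    fix_rows["aoi_raw"].extend(_aoi_label(a) for a in aoi)
                row = {
                    "dyad_id": dyad_id,
                    "interaction_id": inter,
                    "seq_index": s,
                    "referent_id": f"ing{referent:02d}",
                    "repair": int(repair),
                    "reference_onset_ms": onset + t_cursor,
                }
                for k, p in enumerate(PHASES):
                    row[f"{p}_start_ms"] = int(edges[k]) + t_cursor
                    row[f"{p}_end_ms"] = int(edges[k + 1]) + t_cursor
                seq_rows.append(row)
                t_cursor += seq_end + cfg.inter_sequence_gap_ms

    fixations = pd.DataFrame(fix_rows)
    sequences = pd.DataFrame(seq_rows)
    if validate:
        fixations = validate_fixations(fixations)
        sequences = validate_sequences(sequences)
    return SyntheticCorpus(fixations=fixations, sequences=sequences, config=config, seed=seed)


# ---------------------------------------------------------------------------
# Closed-form expectations (deterministic; no Monte Carlo)
# ---------------------------------------------------------------------------

def _same_fixation_prob(delta_ms: float, mean_ms: float, cv: float) -> float:
    """P(two instants ``delta`` apart fall in the same fixation) for a
    stationary renewal process with lognormal dwells: E[(D-delta)+]/E[D]."""
    if delta_ms <= 0:
        return 1.0
    mu, sg = _lognorm_params(mean_ms, cv)
    # partial expectation of a lognormal above a threshold
    upper = mean_ms * stats.norm.cdf((mu + sg * sg - math.log(delta_ms)) / sg)
    tail = 1.0 - stats.lognorm.cdf(delta_ms, sg, scale=math.exp(mu))
    return max(0.0, (upper - delta_ms * tail) / mean_ms)


def _edge_cdf(means_ms: np.ndarray, var_ms2: np.ndarray, k: int):
    """CDF of the k-th phase boundary (sum of the first k gamma durations),
    moment-matched to a single gamma."""
    if k == 0:
        return lambda x: (np.asarray(x, dtype=float) >= 0).astype(float)
    m = float(means_ms[:k].sum())
    v = float(var_ms2[:k].sum())
    shape, scale = m * m / v, v / m
    return lambda x: stats.gamma.cdf(np.maximum(np.asarray(x, dtype=float), 0.0), shape, scale=scale)


_TIMELINE_CACHE: dict = {}


def _timeline(cfg: GeneratorConfig, cell_ms: int = 10):
    """Probabilistic sequence timeline in expectation over the generator's
    randomness (no Monte Carlo).

    Phase boundaries are sums of gamma durations, so a cell at absolute time
    ``t`` belongs to each phase with a probability derived from
    moment-matched partial-sum CDFs; the per-cell instructor and worker
    category distributions mix the per-phase distributions with those
    weights and fold in the referential-timing mechanics (anticipatory
    referent suppression/forcing for the instructor, latency
    suppression/forcing for the worker) in expectation over both the
    lead/latency draws and the reference-onset location.
    """
    key = (id(cfg), cell_ms)
    cached = _TIMELINE_CACHE.get(key)
    if cached is not None:
        return cached
    means = np.array([cfg.phase_duration_mean_s[p] * 1000.0 for p in PHASES])
    var = (means * cfg.phase_duration_cv) ** 2
    total = float(means.sum() + 4.0 * math.sqrt(var.sum()))
    t = np.arange(cell_ms / 2.0, total, cell_ms)
    F = [np.clip(_edge_cdf(means, var, k)(t), 0.0, 1.0) for k in range(6)]
    W = np.stack([np.clip(F[k] - F[k + 1], 0.0, None) for k in range(5)], axis=1)
    in_seq = np.clip(1.0 - F[5], 1e-12, 1.0)
    Wn = W / in_seq[:, None]

    p_i = np.vstack([cfg.instructor_p(p) for p in PHASES])
    p_w = np.vstack([cfg.worker_p(p) for p in PHASES])

    def no_ref(p):
        q = p.copy()
        q[:, _REF] = 0.0
        return q / q.sum(axis=1, keepdims=True)

    p_i_nr, p_w_nr = no_ref(p_i), no_ref(p_w)
    d_mean = cfg.dwell_mean_ms

    # reference onset = first phase boundary; integrate the lead/latency
    # lognormals against its distribution on a fine grid
    m1, v1 = means[0], var[0]
    shape1, scale1 = m1 * m1 / v1, v1 / m1
    xg = np.linspace(stats.gamma.ppf(1e-5, shape1, scale=scale1),
                     stats.gamma.ppf(1.0 - 1e-5, shape1, scale=scale1), 400)
    wg = stats.gamma.pdf(xg, shape1, scale=scale1)
    wg = wg / wg.sum()

    def _mix_cdf(mean_s: float, cv: float, sign: int, disabled: float):
        """P(onset + sign*L <= q) for query times q (vectorised)."""
        if mean_s <= 0:
            return lambda q: np.full_like(np.asarray(q, dtype=float), disabled)
        mu, sg = _lognorm_params(mean_s * 1000.0, cv)

        def cdf(q):
            q = np.atleast_1d(np.asarray(q, dtype=float))
            if sign > 0:
                # P(onset + L <= q) = E_onset[ F_L(q - onset) ]
                d = np.maximum(q[:, None] - xg[None, :], 0.0)
                FL = stats.lognorm.cdf(d, sg, scale=math.exp(mu))
            else:
                # P(onset - L <= q) = E_onset[ 1 - F_L(onset - q) ]
                d = np.maximum(xg[None, :] - q[:, None], 0.0)
                FL = 1.0 - stats.lognorm.cdf(d, sg, scale=math.exp(mu))
            return FL @ wg

        return cdf

    # instructor: forced referent fixation starts at onset - L_i
    Fi = _mix_cdf(cfg.instructor_ref_lead_mean_s, cfg.instructor_ref_lead_cv, -1, 1.0)
    p_started_i = Fi(t)  # P(forced fixation has started by t)
    p_supp_i = np.clip(1.0 - p_started_i, 0.0, 1.0)
    p_forced_i = np.clip(p_started_i - Fi(t - d_mean), 0.0, 1.0)
    free_i = np.clip(1.0 - p_supp_i - p_forced_i, 0.0, 1.0)
    pi_i = p_supp_i[:, None] * (Wn @ p_i_nr) + free_i[:, None] * (Wn @ p_i)
    pi_i[:, _REF] += p_forced_i

    # worker: forced referent fixation starts at onset + L_w
    Fw = _mix_cdf(cfg.worker_ref_latency_mean_s, cfg.worker_ref_latency_cv, +1, 1.0)
    p_started_w = Fw(t)
    p_supp_w = np.clip(1.0 - p_started_w, 0.0, 1.0)
    p_forced_w = np.clip(p_started_w - Fw(t - d_mean), 0.0, 1.0)
    free_w = np.clip(1.0 - p_supp_w - p_forced_w, 0.0, 1.0)
    pi_w = p_supp_w[:, None] * (Wn @ p_w_nr) + free_w[:, None] * (Wn @ p_w)
    pi_w[:, _REF] += p_forced_w

    out = (t, W, 1.0 - F[5], pi_i, pi_w, p_supp_w, total)
    if len(_TIMELINE_CACHE) > 16:
        _TIMELINE_CACHE.clear()
    _TIMELINE_CACHE[key] = out
    return out


def _alignment_parts(
    cfg: GeneratorConfig, phase: str, lag_ms: int, cell_ms: int = 10, match: str = "aoi"
) -> tuple[float, float]:
    """Expected (numerator, denominator) cell sums for the same-target
    alignment of one phase at one lag; see :func:`expected_alignment`.

    ``match="aoi"`` compares gaze objects (independent "other" fixations
    coincide with probability 1/(n_ingredients - 1)); ``match="category"``
    compares the four-category codes (any two "other" fixations match).
    """
    t, W, in_seq, pi_i, pi_w, p_supp_w, total = _timeline(cfg, cell_ms)
    w_phase = W[:, PHASES.index(phase)]
    d_mean, cv = cfg.dwell_mean_ms, cfg.dwell_cv
    # a successful copy lasts the instructor's residual dwell (length-biased
    # interval, uniform entry point: mean * (1 + cv^2) / 2), while fallback
    # and marginal fixations run full dwells, so the time share of coupled
    # gaze is below rho and depends on the copy success mass at each cell
    resid = d_mean * (1.0 + cv * cv) / 2.0
    o_match = 1.0 / max(1, cfg.n_ingredients - 1) if match == "aoi" else 1.0
    rho_g = np.array([cfg.coupling_rho[p] for p in PHASES])
    lam_g = np.array([float(cfg.lead_ms[p]) for p in PHASES])
    a_g = np.array([_same_fixation_prob(abs(lag_ms - lam_g[g]), d_mean, cv) for g in range(5)])
    p_idx = PHASES.index(phase)

    def cell(x: float) -> int:
        return min(len(t) - 1, max(0, int(x // cell_ms)))

    def p_in_seq_given_t(x: float, tj: float) -> float:
        # P(instant x lies inside the sequence | the cell at tj does);
        # instants before tj are inside whenever the cell is, instants after
        # tj survive with the conditional tail ratio of the end distribution
        if x < 0:
            return 0.0
        if x <= tj:
            return 1.0
        return float(in_seq[cell(x)] / max(in_seq[cell(tj)], 1e-12))

    num = den = 0.0
    for j in np.nonzero(w_phase > 1e-6)[0]:
        tj = t[j]
        cmp_t = tj - lag_ms
        if cmp_t < 0:
            continue  # shifted partner before the sequence start
        # pooling weight: P(cell in phase) * P(compared instant still inside
        # the sequence)
        wj = w_phase[j] * p_in_seq_given_t(cmp_t, tj)
        if wj <= 1e-9:
            continue
        pc = pi_i[cell(cmp_t)]  # instructor distribution at the compared instant
        pc_coded = 1.0 - pc[_UNM]
        pw_bg = pi_w[j]
        supp = p_supp_w[j]
        bg_num = float(
            pw_bg[_REF] * pc[_REF]
            + pw_bg[_OTH] * pc[_OTH] * o_match
            + pw_bg[_TGT] * pc[_TGT]
            + pw_bg[_PER] * pc[_PER]
        )
        bg_den = float((1.0 - pw_bg[_UNM]) * pc_coded)

        # the coupling regime is taken from the pooled phase itself;
        # fixations straddling the phase onset carry the previous phase's
        # regime for a residual-dwell sliver, but coupling chains re-anchor
        # at the first post-boundary fixation, so the own-phase
        # approximation is the best first-order model (see docs/methods.md
        # for measured residuals)
        for g, vg in ((p_idx, 1.0),):
            src_t = tj - lam_g[g]
            rho_eff = rho_g[g] * p_in_seq_given_t(src_t, tj)
            if rho_eff <= 0.0:
                num += wj * vg * bg_num
                den += wj * vg * bg_den
                continue
            psrc = pi_i[cell(src_t)]
            a_fix = a_g[g]
            # a coupled copy of category c succeeds unless c is a suppressed
            # referent or partner-directed gaze (fallback to the marginal);
            # copies of unmapped gaze are taken but leave the worker uncoded
            c_num = c_den = 0.0
            for c in (_REF, _OTH, _TGT):
                w = psrc[c] * (1.0 - supp) if c == _REF else psrc[c]
                if w <= 0.0:
                    continue
                m_c = o_match if c == _OTH else 1.0  # same-object prob across fixations
                c_num += w * (a_fix + (1.0 - a_fix) * pc[c] * m_c)
                c_den += w * (a_fix + (1.0 - a_fix) * pc_coded)
            fb = psrc[_REF] * supp + psrc[_PER]
            copy_mass = 1.0 - fb  # coded copies + copies of unmapped gaze
            S_time = rho_eff * copy_mass * resid
            S_time = S_time / (S_time + (rho_eff * fb + 1.0 - rho_eff) * d_mean)
            num += wj * vg * (S_time / copy_mass * c_num + (1.0 - S_time) * bg_num)
            den += wj * vg * (S_time / copy_mass * c_den + (1.0 - S_time) * bg_den)
    return num, den


def expected_alignment(
    config: GeneratorConfig, phase: str, lag_ms: int, cell_ms: int = 10, match: str = "aoi"
) -> float:
    """Deterministic expectation of the same-target alignment fraction for
    one phase at one lag, under the generator's own model.

    Evaluated on the mean-duration timeline: for each time cell of the phase
    the worker's code distribution -- a mixture of lead-shifted instructor
    copies and marginal draws, with the referent-latency suppression applied
    in expectation -- is compared with the instructor's code distribution at
    ``t - lag``.  The fraction is conditional on both streams being coded,
    matching :func:`gazecoord.lag_alignment.alignment_curve`.  Lags away
    from the configured lead are linked through the same-fixation
    probability of a stationary lognormal renewal process, so the expected
    curve peaks at the lead and decays toward the chance level
    ``sum_k p_I(k) p_W(k) / (q_I q_W)``.

    No Monte Carlo is involved; this is the calibration oracle for the
    packaged default configuration.
    """
    num, den = _alignment_parts(config, phase, lag_ms, cell_ms, match)
    return num / den if den > 0 else float("nan")


def expected_same_target(
    config: GeneratorConfig, cell_ms: int = 10, match: str = "category"
) -> float:
    """Deterministic expectation of the zero-lag shared-gaze percentage
    pooled over whole sequences on the mean-duration timeline.

    Defaults to category-level matching -- the convention of the
    code-level descriptive statistic -- while ``match="aoi"`` gives the
    stricter same-object variant.
    """
    num = den = 0.0
    for phase in PHASES:
        n, d = _alignment_parts(config, phase, 0, cell_ms, match)
        num += n
        den += d
    return 100.0 * num / den if den > 0 else float("nan")
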