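"""Stochastic simulation of actin propelled by mechanically coupled myosins.

The model describes an actin filament of length L gliding over a lawn of
myosin motors.  The filament exposes ``N = max(1, round(L / delta))`` myosin
binding sites, with ``delta`` the actin helix repeat (0.0355 µm).  Each site
cycles through three states::

    detached --k_attach--> pre-stroke --k_stroke--> post-stroke --k_detach--> detached

The two mechanical transitions move the motor's elastic anchor along the
sliding direction: the main power stroke by ``d_main`` and a secondary step,
executed immediately before detachment, by ``d_second``.  Every bound motor
is a linear spring of stiffness ``kappa`` between its anchor and the rigid
filament, so the filament position ``z`` instantaneously equilibrates to the
mean of the bound anchors.  A mechanical transition therefore changes the
total elastic energy of the motor-filament system by an amount ``dE``
(including re-equilibration of ``z``), and its rate is modulated by a
Boltzmann factor with a dimensionless coupling-impact parameter ``c``::

    rate = k0 * exp(-c * dE / kT)

A motor acting alone always works at its unstrained rates (its strain is
zero at mechanical equilibrium), and ``c = 0`` decouples the ensemble into
independent motors.  Attachment is strain independent; a motor attaches with
zero strain.  Measurement noise is added to ``z`` at the sampling step only,
so simulated frame-to-frame velocities show the same stopped/running
two-population structure as tracked videos.

The kernel is an exact (next-event) Gillespie simulation compiled with
numba.  Condition parameter sets are expressed as multipliers on a baseline
parameter set shipped as a versioned YAML config; the baseline numbers are a
calibrated reconstruction, see ``data/baseline_params.yaml`` and the methods
note.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
import yaml
from numba import njit

from . import features as _features

__all__ = [
    "MotorParams",
    "SimTrajectory",
    "CONDITION_MULTIPLIERS",
    "baseline_params",
    "condition_params",
    "n_sites",
    "equilibrate",
    "stroke_rate",
    "detach_rate",
    "gillespie_run",
    "simulate_condition",
    "parameter_sweep",
]

#: Actin helix repeat used as the binding-site spacing (µm).
SITE_SPACING_UM = 0.0355

#: Thermal energy at 30 degC (pN nm).
KT_PN_NM = 4.186


@dataclass(frozen=True)
class MotorParams:
    """Kinetic and mechanical parameters of the coupled-myosin model.

    Rates are unstrained rates in 1/s, distances in nm, stiffness in pN/nm.
    ``noise_sigma_nm`` is the standard deviation of the positional
    measurement noise added to each sampled filament position.
    """

    k_attach: float
    k_stroke: float
    k_detach: float
    c_coupling: float
    d_main_nm: float
    d_second_nm: float
    kappa_pn_nm: float
    site_spacing_um: float = SITE_SPACING_UM
    kT_pn_nm: float = KT_PN_NM
    noise_sigma_nm: float = 10.0
    #: Width of the Boltzmann-distributed initial strain at attachment;
    #: negative means "use sqrt(kT/kappa)", the thermal positional spread
    #: of the unbound head.
    sigma_attach_nm: float = -1.0
    #: Per-site rate (1/s) of the first attachment to a fully released
    #: filament.  While at least one motor holds the filament down, heads
    #: rebind at ``k_attach`` per free site; a filament with no bound motor
    #: is only loosely confined near the surface and re-engages much more
    #: slowly, at total rate ``n_sites * k_reengage``.
    k_reengage: float = 0.3

    @property
    def attach_spread_nm(self) -> float:
        if self.sigma_attach_nm < 0:
            return math.sqrt(self.kT_pn_nm / self.kappa_pn_nm)
        return self.sigma_attach_nm

    def __post_init__(self):
        if min(self.k_attach, self.k_stroke, self.k_detach) < 0:
            raise ValueError("rates must be non-negative")
        if self.d_main_nm <= 0 or self.d_second_nm < 0:
            raise ValueError("d_main must be > 0, d_second >= 0")
        if self.c_coupling < 0:
            raise ValueError("c_coupling must be >= 0")

    def with_multipliers(self, **mult: float) -> "MotorParams":
        """Return a copy with named fields multiplied (e.g. k_stroke=1.15)."""
        changes = {}
        for name, m in mult.items():
            changes[name] = getattr(self, name) * m
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


#: Condition-specific multipliers on the baseline parameter set.  The three
#: regulated actin/tropomyosin combinations alter, respectively: all three
#: kinetic rates; the coupling impact; the unloaded detachment rate together
#: with the coupling impact.
CONDITION_MULTIPLIERS: dict[str, dict[str, float]] = {
    "baseline": {},
    "alphaA-TmAlpha": {"k_attach": 1.15, "k_stroke": 1.15, "k_detach": 1.15},
    "gammaA-TmAlpha": {"c_coupling": 1.2},
    "gammaA-TmBeta": {"k_detach": 0.75, "c_coupling": 0.8},
}


def baseline_params() -> MotorParams:
    """Load the calibrated baseline parameter set from the versioned config."""
    ref = importlib.resources.files("actomotility") / "data" / "baseline_params.yaml"
    doc = yaml.safe_load(ref.read_text())
    return MotorParams(**doc["params"])


def condition_params(name: str, base: MotorParams | None = None) -> MotorParams:
    """Parameter set for a named experimental condition.

    ``baseline`` returns the base set unchanged; the regulated conditions
    apply their published multipliers to the baseline.
    """
    if name not in CONDITION_MULTIPLIERS:
        raise KeyError(
            f"unknown condition {name!r}; known: {sorted(CONDITION_MULTIPLIERS)}")
    if base is None:
        base = baseline_params()
    return base.with_multipliers(**CONDITION_MULTIPLIERS[name])


def n_sites(L_um: float, spacing_um: float = SITE_SPACING_UM) -> int:
    """Number of accessible myosin binding sites on a filament of length L."""
    if L_um <= 0:
        raise ValueError("filament length must be positive")
    return max(1, int(round(L_um / spacing_um)))


# ---------------------------------------------------------------------------
# Elastic bookkeeping (python-level mirrors of the kernel formulas, used by
# tests and by callers that want single-event energetics)
# ---------------------------------------------------------------------------

def equilibrate(anchors_nm) -> float:
    """Elastic-equilibrium filament position for equal-stiffness springs.

    With every bound motor a spring of the same stiffness, the total elastic
    energy ``sum kappa/2 (z - a_i)^2`` is minimal at the mean anchor.
    """
    a = np.asarray(anchors_nm, dtype=float)
    if a.size == 0:
        raise ValueError("no bound motors; filament position is unchanged")
    return float(np.mean(a))


def stroke_energy(strain_nm: float, n_bound: int, p: MotorParams) -> float:
    """Elastic-energy change if a pre-stroke motor with given strain strokes.

    ``strain = z - a_i`` for the stroking motor; the filament re-equilibrates
    after the anchor moves by ``d_main``.
    """
    d = p.d_main_nm
    n = n_bound
    return p.kappa_pn_nm * (-d * strain_nm + d * d * (n - 1) / (2.0 * n))


def detach_energy(strain_nm: float, n_bound: int, p: MotorParams) -> float:
    """Elastic-energy change of executing the secondary pre-detachment step.

    Only the mechanical work of the step itself (anchor moves by
    ``d_second``, filament re-equilibrates) modulates the rate; the elastic
    energy released when the bond finally breaks is dissipated and is not
    rate-modulating.  A post-stroke motor whose anchor is ahead of the
    filament (negative strain) therefore detaches more slowly and acts as a
    brake -- the microscopic origin of stops in the coupled ensemble.
    """
    d = p.d_second_nm
    n = n_bound
    return p.kappa_pn_nm * (-d * strain_nm + d * d * (n - 1) / (2.0 * n))


def stroke_rate(strain_nm: float, n_bound: int, p: MotorParams) -> float:
    """Strain-dependent main power-stroke rate."""
    dE = stroke_energy(strain_nm, n_bound, p)
    return p.k_stroke * math.exp(_clip(-p.c_coupling * dE / p.kT_pn_nm))


def detach_rate(strain_nm: float, n_bound: int, p: MotorParams) -> float:
    """Strain-dependent rate of the secondary pre-detachment step."""
    dE = detach_energy(strain_nm, n_bound, p)
    return p.k_detach * math.exp(_clip(-p.c_coupling * dE / p.kT_pn_nm))


def _clip(x: float, lim: float = 50.0) -> float:
    return min(max(x, -lim), lim)


# ---------------------------------------------------------------------------
# Gillespie kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gillespie_kernel(n_sites, t_end, dt, k_a, k_re, k_s, k_d, c, d1, d2,
                      kappa, kT, sig_a, seed, record_events, max_events):
    """Exact next-event simulation; returns sampled z and occupancies.

    State is kept as parallel arrays over currently bound motors: ``kind``
    (1 pre-stroke, 2 post-stroke) and ``strain`` (z - anchor, nm).  All
    event energetics reduce to closed forms in the acting motor's strain and
    the bound count, because z always sits at the mean anchor.
    """
    np.random.seed(seed)
    n_samples = int(round(t_end / dt)) + 1
    zs = np.empty(n_samples)
    n_pre_s = np.zeros(n_samples, np.int64)
    n_post_s = np.zeros(n_samples, np.int64)
    ev_t = np.empty(max_events if record_events else 1)
    ev_kind = np.empty(max_events if record_events else 1, np.int8)
    n_ev = 0

    strain = np.zeros(n_sites)
    kind = np.zeros(n_sites, np.int8)
    n_b = 0
    n_pre = 0
    z = 0.0
    t = 0.0
    zs[0] = 0.0
    next_idx = 1
    rates = np.empty(n_sites)

    while next_idx < n_samples:
        if n_b == 0:
            # released filament: slow re-engagement, proportional to length
            total = k_re * n_sites
        else:
            total = k_a * (n_sites - n_b)
        attach_rate = total
        for i in range(n_b):
            n = n_b
            s = strain[i]
            if kind[i] == 1:
                dE = kappa * (-d1 * s + d1 * d1 * (n - 1) / (2.0 * n))
                x = -c * dE / kT
                if x > 50.0:
                    x = 50.0
                elif x < -50.0:
                    x = -50.0
                r = k_s * math.exp(x)
            else:
                dE = kappa * (-d2 * s + d2 * d2 * (n - 1) / (2.0 * n))
                x = -c * dE / kT
                if x > 50.0:
                    x = 50.0
                elif x < -50.0:
                    x = -50.0
                r = k_d * math.exp(x)
            rates[i] = r
            total += r

        if total <= 0.0:
            # absorbing: nothing can happen any more
            while next_idx < n_samples:
                zs[next_idx] = z
                n_pre_s[next_idx] = n_pre
                n_post_s[next_idx] = n_b - n_pre
                next_idx += 1
            break

        tau = -math.log(np.random.random()) / total
        t_new = t + tau
        while next_idx < n_samples and next_idx * dt <= t_new:
            zs[next_idx] = z
            n_pre_s[next_idx] = n_pre
            n_post_s[next_idx] = n_b - n_pre
            next_idx += 1
        if next_idx >= n_samples:
            break
        t = t_new

        u = np.random.random() * total
        if u < attach_rate:
            # attachment at a free site; the head binds with a thermally
            # distributed initial strain and the filament re-equilibrates
            s0 = sig_a * np.random.standard_normal() if sig_a > 0.0 else 0.0
            shift = s0 / (n_b + 1)
            for k in range(n_b):
                strain[k] -= shift
            z -= shift
            strain[n_b] = s0 - shift
            kind[n_b] = 1
            n_b += 1
            n_pre += 1
            if record_events and n_ev < max_events:
                ev_t[n_ev] = t
                ev_kind[n_ev] = 1
                n_ev += 1
        else:
            acc = attach_rate
            chosen = n_b - 1
            for i in range(n_b):
                acc += rates[i]
                if u < acc:
                    chosen = i
                    break
            n = n_b
            if kind[chosen] == 1:
                # main power stroke: anchor += d1, z += d1/n
                shift = d1 / n
                for k in range(n_b):
                    strain[k] += shift
                strain[chosen] -= d1
                kind[chosen] = 2
                z += shift
                n_pre -= 1
                if record_events and n_ev < max_events:
                    ev_t[n_ev] = t
                    ev_kind[n_ev] = 2
                    n_ev += 1
            else:
                # secondary step then detachment
                shift = d2 / n
                for k in range(n_b):
                    strain[k] += shift
                strain[chosen] -= d2
                z += shift
                if n > 1:
                    rel = strain[chosen] / (n - 1)
                    z += rel
                    for k in range(n_b):
                        strain[k] += rel
                strain[chosen] = strain[n_b - 1]
                kind[chosen] = kind[n_b - 1]
                n_b -= 1
                if record_events and n_ev < max_events:
                    ev_t[n_ev] = t
                    ev_kind[n_ev] = 3
                    n_ev += 1

    return zs, n_pre_s, n_post_s, ev_t[:n_ev], ev_kind[:n_ev]


@dataclass
class SimTrajectory:
    """Simulated filament displacement sampled at the analysis resolution.

    ``z_um`` carries the measurement noise used for feature extraction;
    ``z_true_um`` is the noise-free mechanical displacement.  ``n_pre`` /
    ``n_post`` are the bound-motor counts by state at the sample times.
    """

    t_s: np.ndarray
    z_um: np.ndarray
    z_true_um: np.ndarray
    n_pre: np.ndarray
    n_post: np.ndarray
    L_um: float
    params: MotorParams
    seed: int
    event_times: np.ndarray | None = None
    event_kinds: np.ndarray | None = None

    @property
    def n_bound(self) -> np.ndarray:
        return self.n_pre + self.n_post

    def v_f2f(self) -> np.ndarray:
        """Frame-to-frame speeds |dz|/dt (µm/s) from the noisy samples."""
        dt = self.t_s[1] - self.t_s[0]
        return np.abs(np.diff(self.z_um)) / dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.t_s, "z_um": self.z_um,
            "z_true_um": self.z_true_um,
            "n_bound": self.n_bound,
        })


def gillespie_run(params: MotorParams, L_um: float, T_s: float, seed: int, *,
                  dt_s: float = 1 / 3, record_events: bool = False,
                  max_events: int = 2_000_000) -> SimTrajectory:
    """Simulate one filament of length ``L_um`` for ``T_s`` seconds.

    Runs the exact stochastic simulation and samples the filament position
    on the ``dt_s`` grid, adding Gaussian measurement noise of width
    ``params.noise_sigma_nm`` (µm-converted) to each sample.  Fully
    reproducible for a fixed seed.
    """
    if T_s <= 0:
        raise ValueError("simulation time must be positive")
    N = n_sites(L_um, params.site_spacing_um)
    kseed = int(seed) % (2 ** 31 - 1)
    zs, n_pre, n_post, ev_t, ev_k = _gillespie_kernel(
        N, T_s, dt_s, params.k_attach, params.k_reengage, params.k_stroke,
        params.k_detach, params.c_coupling, params.d_main_nm,
        params.d_second_nm, params.kappa_pn_nm, params.kT_pn_nm,
        params.attach_spread_nm, kseed, record_events, max_events)
    t = np.arange(zs.size) * dt_s
    rng = np.random.default_rng(kseed + 1)
    noise = rng.normal(0.0, params.noise_sigma_nm, zs.size)
    traj = SimTrajectory(
        t_s=t, z_um=(zs + noise) / 1000.0, z_true_um=zs / 1000.0,
        n_pre=n_pre, n_post=n_post, L_um=L_um, params=params, seed=seed)
    if record_events:
        traj.event_times = ev_t
        traj.event_kinds = ev_k
    return traj


def simulate_condition(params: MotorParams, n_filaments: int, T_s: float,
                       seed: int, *, condition: str = "",
                       length_range=(0.3, 3.25), lengths=None,
                       dt_s: float = 1 / 3, cut: float | None = None,
                       ) -> pd.DataFrame:
    """Simulate a condition and reduce it to a per-filament record table.

    Filament lengths are drawn uniformly over ``length_range`` (or given
    explicitly).  Every trajectory is converted to a v_f2f series and fed
    through the standard feature pipeline: a two-Gaussian velocity cut
    fitted to the pooled condition velocities (unless ``cut`` is given),
    run/stop segmentation, and per-filament feature extraction.  The
    returned table has the same schema as the video-analysis output, so the
    windowing and statistics modules run unchanged on it.
    """
    if n_filaments < 1:
        raise ValueError("need at least one filament")
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = rng.uniform(length_range[0], length_range[1], n_filaments)
    else:
        lengths = np.asarray(lengths, dtype=float)
        n_filaments = lengths.size
    sub_seeds = rng.integers(0, 2 ** 31 - 2, size=n_filaments)
    series, v_traces = [], []
    for L, s in zip(lengths, sub_seeds):
        traj = gillespie_run(params, float(L), T_s, int(s), dt_s=dt_s)
        series.append(traj.v_f2f())
        # the simulated filament is a point on the sliding axis: the tip
        # path length equals the total sampled displacement path
        v_traces.append(np.sum(np.abs(np.diff(traj.z_um))) / (T_s))
    df = _features.records_from_series(
        series, lengths, dt_s, cut=cut, condition=condition,
        v_traces=v_traces)
    df.attrs["T_s"] = T_s
    df.attrs["seed"] = seed
    return df


def parameter_sweep(base: MotorParams, param: str, lo_mult: float,
                    hi_mult: float, n_steps: int = 15, *,
                    n_filaments: int = 60, T_s: float = 20.0, seed: int = 0,
                    length_range=(0.3, 3.25), dt_s: float = 1 / 3,
                    n_windows: int = 25, cut: float | None = None) -> dict:
    """Sweep one parameter and return length-resolved curves per multiplier.

    For each of ``n_steps`` equally spaced multipliers in
    ``[lo_mult, hi_mult]``, the condition is simulated and reduced to the
    four windowed feature curves; used to locate multipliers that mimic
    experimental fold changes.
    """
    if lo_mult >= hi_mult:
        raise ValueError("lo_mult must be < hi_mult")
    mults = np.linspace(lo_mult, hi_mult, n_steps)
    out = {}
    for j, m in enumerate(mults):
        p = base.with_multipliers(**{param: float(m)})
        rec = simulate_condition(p, n_filaments, T_s, seed + j,
                                 condition=f"{param}x{m:.3f}",
                                 length_range=length_range, dt_s=dt_s, cut=cut)
        out[float(m)] = _features.windowed_curves(
            rec, length_range=length_range, n_windows=n_windows)
    return out
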