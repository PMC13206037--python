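"""Synthetic binary-fission communities with known informational regimes.

Stands in for confined-microchamber recordings of clonal ciliate
communities: a founder divides synchronously into 2, 4, 8, ... cells, and
each cell carries a kinetic-energy (KE) time series whose statistical
coupling to its siblings is controlled by a regime specification with known
ground truth.  Three regimes are realizable:

``coupled``
    All contemporaneous cells integrate a *persistent* shared AR(1) drive
    into their own dynamics.  Because each cell's state accumulates the
    drive's history, the sibling mean-field is largely redundant with the
    cell's own past: NTIC >> 0 while MI(X';C) >> 0.

``information_closed``
    Cells share an *iid common pulse* eta_t that enters the observed log-KE
    contemporaneously (weight ``pulse_now``) and again one sample later
    (weight ``pulse_lag``).  The delayed component makes the sibling
    mean-field genuinely predictive of the focal future through a channel
    nearly orthogonal to the focal's own state (transfer entropy > 0), while
    the weights are chosen so redundancy and synergy balance: MI(X';C) > 0
    with NTIC ~ 0.  A one-step shared innovation fed through the *dynamics*
    cannot produce this signature — in a synchronous symmetric AR(1)
    community the focal state is a sufficient statistic for its own
    transition, forcing TE(C->X) = 0 — which is why the pulse acts at the
    observation level with a lag.

``independent``
    No shared component at all.

The latent process is log-KE; the KE marginal is shaped by ``marginal_type``
(lognormal-like ``heavy_tailed`` via exp, or exponential-like
``steep_decay`` via softplus), and a trapezoidal envelope slows cells near
birth and division.  All randomness derives from one master seed through a
documented per-cell / per-stream sub-seeding scheme, so regeneration with
the same seed is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .kinematics import CellSeries
from .lineage import LineageTable, expand_binary_tree

__all__ = [
    "RegimeSpec",
    "SeriesBundle",
    "simulate_lineage",
    "simulate_community",
    "regime_kernel_step",
    "ar1",
]

REGIMES = ("coupled", "information_closed", "independent")

#: dt of the generated grid, in seconds.  The generator emits series directly
#: on the analysis grid (0.5 s = five 100-ms recording frames), where the
#: regime calibration is defined.
GENERATOR_DT = 0.5


@dataclass(frozen=True)
class RegimeSpec:
    """Generative parameters realizing one informational regime.

    All coefficients act on the latent log-KE scale.  ``context_coefficient``
    is the single coupling amplitude: it scales the persistent-drive coupling
    in the coupled regime and the common-pulse weights in the
    information-closed regime; 0 turns off all sibling structure.
    """

    regime_label: str
    self_coefficient: float = 0.8
    context_coefficient: float = 0.0
    shared_innovation_sd: float = 0.0
    private_noise_sd: float = 1.0
    drive_persistence: float = 0.9
    pulse_now: float = 0.85
    pulse_lag: float = 1.90
    marginal_type: str = "heavy_tailed"
    envelope_depth: float = 0.3
    envelope_fraction: float = 0.1
    inherit_perturbation: float = 0.0

    def __post_init__(self) -> None:
        if self.regime_label not in REGIMES:
            raise ValueError(f"unknown regime {self.regime_label!r}")
        if not 0 < self.self_coefficient < 1:
            raise ValueError("self_coefficient must be in (0, 1)")
        if self.context_coefficient < 0:
            raise ValueError("context_coefficient must be >= 0")
        if self.regime_label == "independent" and (
            self.context_coefficient != 0 or self.shared_innovation_sd != 0
        ):
            raise ValueError(
                "independent regime requires context_coefficient = 0 and "
                "shared_innovation_sd = 0"
            )
        if self.marginal_type not in ("steep_decay", "heavy_tailed"):
            raise ValueError(f"unknown marginal_type {self.marginal_type!r}")

    # -- canonical regimes (coefficients fixed by the Gaussian design
    #    calculation; see docs/methods.md) --------------------------------

    @classmethod
    def coupled(cls, **kw) -> "RegimeSpec":
        kw.setdefault("self_coefficient", 0.8)
        kw.setdefault("context_coefficient", 0.45)
        kw.setdefault("shared_innovation_sd", 1.0)
        kw.setdefault("drive_persistence", 0.9)
        return cls(regime_label="coupled", **kw)

    @classmethod
    def information_closed(cls, **kw) -> "RegimeSpec":
        kw.setdefault("self_coefficient", 0.85)
        kw.setdefault("context_coefficient", 1.0)
        kw.setdefault("shared_innovation_sd", 1.0)
        return cls(regime_label="information_closed", **kw)

    @classmethod
    def independent(cls, **kw) -> "RegimeSpec":
        return cls(regime_label="independent", **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SeriesBundle:
    """A simulated community: genealogy, per-cell KE series, ground truth."""

    lineage: LineageTable
    series: dict[int, CellSeries]
    truth: dict[int, str]
    seed: int
    dt: float = GENERATOR_DT

    def write(self, outdir: str | Path) -> None:
        """Write lineage CSV, long-form KE CSV and a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.lineage.to_csv(outdir / "lineage.csv")
        import pandas as pd

        pd.concat(
            [
                pd.DataFrame({"cell_id": cid, "frame": s.frames, "ke": s.values})
                for cid, s in sorted(self.series.items())
            ],
            ignore_index=True,
        ).to_csv(outdir / "series.csv", index=False)
        sidecar = {"seed": self.seed, "dt": self.dt, "truth": self.truth}
        (outdir / "bundle.json").write_text(json.dumps(sidecar, indent=2, default=str))


def simulate_lineage(
    generations: int,
    frames_per_generation: int,
    seed: int = 0,
    division_jitter: float = 0.02,
) -> LineageTable:
    """Full binary-fission genealogy with synchronized, jittered divisions.

    Generation g holds 2**g cells; divisions of generation g happen near
    frame (g+1) * frames_per_generation, each jittered uniformly by up to
    ``division_jitter`` of the generation length.  Terminal cells are
    observed for one generation length.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if frames_per_generation <= 0:
        raise ValueError(
            f"frames_per_generation must be positive, got {frames_per_generation}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11]))
    F = int(frames_per_generation)
    records = []
    birth = {0: 0}
    for cid, parent, g in expand_binary_tree(generations):
        b = birth[cid]
        if g < generations:
            jit = int(round(rng.uniform(-division_jitter, division_jitter) * F))
            division = max(b + 3, (g + 1) * F + jit)
            end = division
            birth[2 * cid + 1] = division
            birth[2 * cid + 2] = division
        else:
            division = np.nan
            end = b + F
        records.append(
            dict(
                cell_id=cid,
                parent_id=np.nan if parent is None else parent,
                generation=g,
                birth_frame=b,
                division_frame=division,
                end_frame=end,
            )
        )
    return LineageTable.from_records(records)


def regime_kernel_step(
    state: float,
    context: float,
    shared_innovation: float,
    spec: RegimeSpec,
    rng_draw: float,
) -> float:
    """One latent log-KE transition (pure, deterministic given its inputs).

    next = a * state + c * context + shared_innovation + sigma * rng_draw,
    with a = ``self_coefficient``, c = ``context_coefficient`` and sigma =
    ``private_noise_sd``.  The coupled regime passes the persistent shared
    drive as ``context``; the independent regime passes zeros.  (The
    information-closed pulse acts at the observation layer, not here.)
    """
    return (
        spec.self_coefficient * state
        + spec.context_coefficient * context
        + shared_innovation
        + spec.private_noise_sd * rng_draw
    )


def _envelope(n: int, depth: float, fraction: float) -> np.ndarray:
    """Trapezoid multiplier: ``depth`` at birth/division edges, 1 in the bulk."""
    if n == 0:
        return np.ones(0)
    ramp = max(1, int(round(fraction * n)))
    m = np.ones(n)
    up = np.linspace(depth, 1.0, ramp, endpoint=False)
    m[:ramp] = up
    m[n - ramp :] = up[::-1]
    return m


def _ke_transform(latent: np.ndarray, marginal_type: str) -> np.ndarray:
    if marginal_type == "heavy_tailed":
        return np.exp(latent)
    # softplus keeps KE >= 0 with an exponential-like upper tail
    return np.logaddexp(0.0, latent)


def ar1(n: int, coefficient: float, innovation_sd: float, rng) -> np.ndarray:
    """Stationary AR(1) sample path (used for drives and null cells)."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, innovation_sd / np.sqrt(1.0 - coefficient**2))
    eps = rng.normal(0.0, innovation_sd, n)
    for t in range(1, n):
        x[t] = coefficient * x[t - 1] + eps[t]
    return x


def simulate_community(
    lineage: LineageTable,
    specs: dict[int, RegimeSpec] | RegimeSpec,
    seed: int = 0,
    cell_overrides: dict[int, RegimeSpec] | None = None,
    dt: float = GENERATOR_DT,
) -> SeriesBundle:
    """Simulate KE series for every cell of a lineage.

    ``specs`` maps generation index to a :class:`RegimeSpec` (or one spec for
    all generations).  ``cell_overrides`` replaces the spec of individual
    cells — used e.g. to give a subset of daughters perturbed marginals.
    Contemporaneous cells governed by the same regime share one
    shared-innovation stream per generation; daughters inherit their
    parent's terminal latent state at division.

    Sub-seeding: stream ids are derived from the master seed as
    SeedSequence([seed, tag, key]) with tag 1 for shared generation streams
    (key = generation * 8 + regime index) and tag 2 for private cell streams
    (key = cell_id), so any cell's noise is reproducible in isolation.
    """
    if isinstance(specs, RegimeSpec):
        specs = {g: specs for g in range(lineage.generations + 1)}
    cell_overrides = cell_overrides or {}
    horizon = int(lineage.table["end_frame"].max())

    def spec_of(cid: int) -> RegimeSpec:
        if cid in cell_overrides:
            return cell_overrides[cid]
        g = lineage.generation_of(cid)
        if g not in specs:
            raise KeyError(f"no RegimeSpec for generation {g}")
        return specs[g]

    # one shared stream per (generation, regime) over the full horizon, so
    # jittered lifetimes still index a common stream by absolute frame
    shared: dict[tuple[int, str], np.ndarray] = {}
    for cid in lineage.cell_ids:
        sp = spec_of(cid)
        g = lineage.generation_of(cid)
        key = (g, sp.regime_label)
        if key in shared or sp.regime_label == "independent":
            continue
        stream_rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 1, g * 8 + REGIMES.index(sp.regime_label)])
        )
        if sp.regime_label == "coupled":
            shared[key] = ar1(
                horizon, sp.drive_persistence, sp.shared_innovation_sd, stream_rng
            )
        else:  # information_closed: iid common pulse
            shared[key] = stream_rng.normal(0.0, sp.shared_innovation_sd, horizon)

    series: dict[int, CellSeries] = {}
    truth: dict[int, str] = {}
    final_core: dict[int, float] = {}

    for cid in lineage.cell_ids:  # breadth-first: parents precede daughters
        sp = spec_of(cid)
        g = lineage.generation_of(cid)
        b, e = lineage.lifespan(cid)
        n = e - b
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2, cid]))
        xi = rng.normal(0.0, 1.0, n)
        parent = lineage.parent_of(cid)
        core = np.empty(n)
        if parent is None:
            core[0] = rng.normal(
                0.0, sp.private_noise_sd / np.sqrt(1.0 - sp.self_coefficient**2)
            )
        else:
            core[0] = final_core[parent]
        drive = shared.get((g, "coupled"))
        for t in range(1, n):
            ctx = drive[b + t - 1] if (sp.regime_label == "coupled" and drive is not None) else 0.0
            core[t] = regime_kernel_step(core[t - 1], ctx, 0.0, sp, xi[t])
        final_core[cid] = core[-1]

        obs = core
        if sp.regime_label == "information_closed":
            eta = shared[(g, "information_closed")]
            amp = sp.context_coefficient
            now = eta[b : b + n]
            lagged = np.empty(n)
            lagged[0] = eta[b - 1] if b > 0 else 0.0
            lagged[1:] = eta[b : b + n - 1]
            obs = core + amp * (sp.pulse_now * now + sp.pulse_lag * lagged)
        if sp.inherit_perturbation > 0:
            gain = np.exp(rng.normal(0.0, sp.inherit_perturbation))
            offset = rng.normal(0.0, sp.inherit_perturbation)
            obs = gain * obs + offset

        ke = _ke_transform(obs, sp.marginal_type)
        ke = ke * _envelope(n, sp.envelope_depth, sp.envelope_fraction)
        series[cid] = CellSeries(
            cell_id=cid, frames=np.arange(b, e), values=ke, dt=dt, stride=1
        )
        truth[cid] = sp.regime_label

    return SeriesBundle(lineage=lineage, series=series, truth=truth, seed=int(seed), dt=dt)


def simulate_tracks(bundle: SeriesBundle, seed: int = 0) -> dict[int, np.ndarray]:
    """Synthetic 2-D trajectories consistent with a bundle's KE series.

    Each cell performs a random-turning walk whose per-frame speed is
    sqrt(2 KE); running :func:`nticell.kinematics.kinetic_energy` on the
    returned (frame, x, y) arrays recovers the KE series (one sample short).
    """
    out = {}
    for cid, s in bundle.series.items():
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3, cid]))
        speed = np.sqrt(2.0 * s.values)
        theta = np.cumsum(rng.uniform(-0.8, 0.8, len(s)))
        steps = speed[:, None] * np.column_stack([np.cos(theta), np.sin(theta)]) * bundle.dt
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        frames = np.concatenate([s.frames, [s.frames[-1] + 1]])
        out[cid] = np.column_stack([frames, pos])
    return out
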