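"""Seeded synthetic data with known ground truth.

Three generators emulate the data a time-dependent cell-state selection
experiment produces, so every downstream stage can be tested without any
external download:

* secretion traces — baseline drift ``a*t`` switching to post-onset slope
  ``b`` at a per-cell latent onset time, plus iid Gaussian frame noise;
  onset latencies are broad (lognormal) to mimic the hours-wide spread of
  real single-cell secretion onsets;
* state-labelled count matrices — negative-binomial gene counts with
  planted transition-mode gene classes (multiplicative fold-changes on the
  NB mean in the affected states), null genes, and spike-in reference rows
  that are constant in expectation across cells;
* onset/censoring cohorts for survival analysis.

All generators are deterministic given their seed.  Secreting cells are
assigned by quota (the first ``ceil(frac * n)`` cell ids) rather than
per-cell coin flips so that truth-table counts are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import StateCountMatrix
from .errors import ConfigError
from .onset import piecewise_signal
from .trace import SecretionTrace

__all__ = [
    "TraceSimConfig",
    "CountSimConfig",
    "sample_dist",
    "simulate_secretion_traces",
    "simulate_two_channel_traces",
    "simulate_state_counts",
    "simulate_onset_cohort",
    "render_well_stack",
    "MOUSE6_CLASS_EFFECTS",
    "HUMAN5_CLASS_EFFECTS",
]

#: Per-class sign of the log2 fold-change applied to the NB mean in each
#: state (states absent from a map keep the baseline mean).  The four-state
#: (mouse-style) set distinguishes early/late/silent/transient induction
#: and reduction; the three-state (human-style) set lacks a silent state.
MOUSE6_CLASS_EFFECTS: dict[str, dict[str, int]] = {
    "EIG": {"transition": +1, "activated": +1},
    "ERG": {"transition": -1, "activated": -1},
    "LIG": {"activated": +1},
    "LRG": {"activated": -1},
    "SIG": {"silent": +1},
    "TIG": {"transition": +1},
}

HUMAN5_CLASS_EFFECTS: dict[str, dict[str, int]] = {
    "EIG": {"transition": +1, "activated": +1},
    "LIG": {"activated": +1},
    "LEG": {"activated": -1},
    "TRG": {"transition": -1},
    "TIG": {"transition": +1},
}


def sample_dist(spec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` samples from a small declarative distribution spec.

    Supported forms: ``("constant", {"value": v})``,
    ``("lognormal", {"median": m, "sigma": s})`` (sigma in log-units),
    ``("uniform", {"low": a, "high": b})`` and
    ``("exponential", {"mean": m})``.
    """
    try:
        name, params = spec
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"malformed distribution spec {spec!r}") from exc
    if name == "constant":
        return np.full(size, float(params["value"]))
    if name == "lognormal":
        return rng.lognormal(math.log(params["median"]), params["sigma"], size)
    if name == "uniform":
        return rng.uniform(params["low"], params["high"], size)
    if name == "exponential":
        return rng.exponential(params["mean"], size)
    raise ConfigError(f"unknown distribution {name!r}")


# ---------------------------------------------------------------------------
# secretion traces
# ---------------------------------------------------------------------------

@dataclass
class TraceSimConfig:
    """Conditions for simulated secretion traces.

    Defaults reflect a mouse-style run: 4-min scanning over 8 h, a slow
    drift of 0.1 signal-units/h against a post-onset slope of 2.0, frame
    noise 0.04 (per-frame signal-to-noise (b-a)*interval/sd about 3) and
    onset latencies spread lognormally over several hours.
    """

    n_cells: int = 100
    scan_interval_h: float = 4 / 60
    duration_h: float = 8.0
    drift_a: float = 0.1
    slope_b: float = 2.0
    onset_latency_dist: tuple = ("lognormal", {"median": 2.5, "sigma": 0.5})
    frac_secreting: float = 0.6
    noise_sd: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.scan_interval_h <= 0:
            raise ConfigError(f"scan_interval_h must be > 0, got {self.scan_interval_h}")
        if self.duration_h < 10 * self.scan_interval_h:
            raise ConfigError(
                f"duration_h must be >= 10 scan intervals, got {self.duration_h}"
            )
        if not 0.0 <= self.frac_secreting <= 1.0:
            raise ConfigError(f"frac_secreting must be in [0, 1], got {self.frac_secreting}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not self.slope_b > self.drift_a >= 0:
            raise ConfigError(
                f"need slope_b > drift_a >= 0, got b={self.slope_b}, a={self.drift_a}"
            )

    def times(self) -> np.ndarray:
        n_frames = int(np.floor(self.duration_h / self.scan_interval_h + 1e-9))
        return np.arange(1, n_frames + 1) * self.scan_interval_h


def _draw_onsets(config: TraceSimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Latencies truncated 1 h before the end of the scan window so every
    quota-assigned secreting cell has an observable onset."""
    lat = sample_dist(config.onset_latency_dist, n, rng)
    return np.minimum(lat, config.duration_h - 1.0)


def simulate_secretion_traces(
    config: TraceSimConfig,
    channel: str = "ch1",
) -> tuple[list[SecretionTrace], pd.DataFrame]:
    """Simulate per-cell secretion traces with a per-cell onset truth table.

    Returns the traces and a DataFrame (``cell_id``, ``onset_h``) where
    non-secreting cells carry ``NaN``.  The first ``ceil(frac * n)`` cells
    secrete (deterministic quota).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = config.times()
    n_secreting = math.ceil(config.frac_secreting * config.n_cells)
    onsets = _draw_onsets(config, n_secreting, rng)

    traces, truth = [], []
    for i in range(config.n_cells):
        cell_id = f"cell{i:04d}"
        if i < n_secreting:
            clean = piecewise_signal(times, config.drift_a, config.slope_b, onsets[i])
            truth.append((cell_id, float(onsets[i])))
        else:
            clean = config.drift_a * times
            truth.append((cell_id, np.nan))
        noise = rng.normal(0.0, config.noise_sd, times.size) if config.noise_sd else 0.0
        traces.append(
            SecretionTrace(
                cell_id=cell_id,
                times=times,
                signal=clean + noise,
                channel=channel,
                scan_interval_h=config.scan_interval_h,
            )
        )
    truth_df = pd.DataFrame(truth, columns=["cell_id", "onset_h"])
    return traces, truth_df


def simulate_two_channel_traces(
    config: TraceSimConfig,
    lag_dist: tuple = ("constant", {"value": 0.5}),
) -> tuple[list[SecretionTrace], list[SecretionTrace], pd.DataFrame]:
    """Simulate paired traces where channel 2 starts ``lag`` hours after
    channel 1 (lag may be zero or negative).  Both channels share the
    drift/slope/noise model; noise is independent per channel.  The truth
    table records per-cell channel-1 onset and lag (NaN for non-secreting
    cells)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = config.times()
    n_secreting = math.ceil(config.frac_secreting * config.n_cells)
    onsets1 = _draw_onsets(config, n_secreting, rng)
    lags = sample_dist(lag_dist, n_secreting, rng)

    tr1, tr2, truth = [], [], []
    for i in range(config.n_cells):
        cell_id = f"cell{i:04d}"
        if i < n_secreting:
            o1 = onsets1[i]
            o2 = min(max(o1 + lags[i], config.scan_interval_h), config.duration_h - 0.5)
            clean1 = piecewise_signal(times, config.drift_a, config.slope_b, o1)
            clean2 = piecewise_signal(times, config.drift_a, config.slope_b, o2)
            truth.append((cell_id, float(o1), float(o2 - o1)))
        else:
            clean1 = clean2 = config.drift_a * times
            truth.append((cell_id, np.nan, np.nan))
        for clean, chan, dest in ((clean1, "ch1", tr1), (clean2, "ch2", tr2)):
            noise = rng.normal(0.0, config.noise_sd, times.size) if config.noise_sd else 0.0
            dest.append(
                SecretionTrace(
                    cell_id=cell_id,
                    times=times,
                    signal=clean + noise,
                    channel=chan,
                    scan_interval_h=config.scan_interval_h,
                )
            )
    truth_df = pd.DataFrame(truth, columns=["cell_id", "onset_ch1_h", "lag_h"])
    return tr1, tr2, truth_df


def render_well_stack(
    traces: list[SecretionTrace],
    well_radius: int = 4,
    spacing: int = 14,
    base_intensity: float = 100.0,
    background: float = 10.0,
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """Render traces as a synthetic image stack of constant-intensity disk
    wells on a grid (one frame per time point).  Returns the stack, the
    per-cell boolean ROI masks and the frame times.  Useful for exercising
    the image-extraction path end to end."""
    from .imaging import disk_mask

    n = len(traces)
    n_cols = int(math.ceil(math.sqrt(n)))
    n_rows = int(math.ceil(n / n_cols))
    shape = (n_rows * spacing, n_cols * spacing)
    times = traces[0].times
    stack = np.full((times.size,) + shape, background, dtype=float)
    rois: dict[str, np.ndarray] = {}
    for i, tr in enumerate(traces):
        r, c = divmod(i, n_cols)
        center = (r * spacing + spacing // 2, c * spacing + spacing // 2)
        mask = disk_mask(shape, center, well_radius)
        rois[tr.cell_id] = mask
        stack[:, mask] = (base_intensity + tr.signal)[:, None]
    return stack, rois, times


# ---------------------------------------------------------------------------
# state-labelled count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    """Conditions for simulated state-labelled count matrices.

    Planted gene classes modify the per-gene NB mean by a factor
    ``2**effect_log2fc`` (up) or ``2**-effect_log2fc`` (down) in the states
    their transition mode affects.  Spike-in rows have a fixed mean that is
    not modulated by state or library size, mimicking exogenous reference
    RNA added at a constant amount per sample.

    Gene means are absolute by default: a planted gene with baseline 10
    and ``effect_log2fc=2`` has NB mean exactly ``10 * 2**2 = 40`` in its
    induced states (before the per-cell library factor) and null genes
    have a state-independent mean.  With ``relative_abundance=True`` each
    cell's endogenous mean vector is instead rescaled to a common expected
    total, emulating purely compositional measurement where induction of
    one gene necessarily depresses the measured share of every other.
    """

    n_genes_per_class: int = 150
    n_null_genes: int = 2000
    n_cells_per_state: int = 50
    states: tuple[str, ...] = ("pre", "transition", "activated", "silent")
    baseline_mean_dist: tuple = ("lognormal", {"median": 20.0, "sigma": 1.0})
    dispersion: float = 0.2
    effect_log2fc: float = 2.0
    library_size_dist: tuple = ("lognormal", {"median": 1.0, "sigma": 0.3})
    n_spikein: int = 10
    spikein_mean: float = 200.0
    n_donors: int = 1
    seed: int = 0
    relative_abundance: bool = False
    class_effects: Mapping[str, Mapping[str, int]] | None = None

    def resolved_class_effects(self) -> dict[str, dict[str, int]]:
        if self.class_effects is not None:
            return {c: dict(m) for c, m in self.class_effects.items()}
        if "silent" in self.states:
            return {c: dict(m) for c, m in MOUSE6_CLASS_EFFECTS.items()}
        return {c: dict(m) for c, m in HUMAN5_CLASS_EFFECTS.items()}

    def validate(self) -> None:
        for name in ("n_genes_per_class", "n_null_genes", "n_spikein"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_cells_per_state < 1:
            raise ConfigError(f"n_cells_per_state must be >= 1, got {self.n_cells_per_state}")
        if self.n_donors < 1:
            raise ConfigError(f"n_donors must be >= 1, got {self.n_donors}")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be > 0, got {self.dispersion}")
        if self.effect_log2fc < 0:
            raise ConfigError(f"effect_log2fc must be >= 0, got {self.effect_log2fc}")
        required = {"pre", "transition", "activated"}
        if not required.issubset(self.states):
            raise ConfigError(
                f"states must contain {sorted(required)}, got {list(self.states)}"
            )
        for cls, effects in self.resolved_class_effects().items():
            unknown = set(effects) - set(self.states)
            if unknown:
                raise ConfigError(
                    f"class {cls} references unknown states {sorted(unknown)}"
                )


def _nb_sample(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """NB draws parameterised by mean and dispersion (var = mu + disp*mu^2)."""
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mean, 1e-12))
    return rng.negative_binomial(size, p)


def simulate_state_counts(
    config: CountSimConfig,
) -> tuple[StateCountMatrix, pd.DataFrame]:
    """Simulate a gene x cell count matrix with planted transition classes.

    Returns the matrix and a truth table (``gene_id``, ``class``) where
    null genes are labelled ``"null"`` and spike-ins ``"spikein"``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    effects = config.resolved_class_effects()
    classes = list(effects)

    gene_ids, gene_class = [], []
    for cls in classes:
        for j in range(config.n_genes_per_class):
            gene_ids.append(f"{cls.lower()}_{j:04d}")
            gene_class.append(cls)
    for j in range(config.n_null_genes):
        gene_ids.append(f"null_{j:04d}")
        gene_class.append("null")
    for j in range(config.n_spikein):
        gene_ids.append(f"spikein_{j:02d}")
        gene_class.append("spikein")
    n_genes = len(gene_ids)
    spikein_mask = np.array([c == "spikein" for c in gene_class])

    cell_ids, state_labels, donor_labels = [], [], []
    for st in config.states:
        for c in range(config.n_cells_per_state):
            cell_ids.append(f"{st}_{c:03d}")
            state_labels.append(st)
            donor_labels.append(f"d{c % config.n_donors + 1}")
    n_cells = len(cell_ids)

    baseline = sample_dist(config.baseline_mean_dist, n_genes, rng)
    baseline[spikein_mask] = config.spikein_mean
    lib = sample_dist(config.library_size_dist, n_cells, rng)

    # log2 fold-change sign per gene per state
    fc_sign = np.zeros((n_genes, len(config.states)))
    state_index = {s: i for i, s in enumerate(config.states)}
    for g, cls in enumerate(gene_class):
        for st, sign in effects.get(cls, {}).items():
            fc_sign[g, state_index[st]] = sign

    state_of_cell = np.array([state_index[s] for s in state_labels])
    mean = baseline[:, None] * 2.0 ** (config.effect_log2fc * fc_sign[:, state_of_cell])
    endo = ~spikein_mask
    if config.relative_abundance and endo.any():
        # Means are relative abundances: rescale each cell's endogenous
        # expectation to a common total, so composition (hence CPM) carries
        # the planted effects and null genes stay flat.
        target_total = baseline[endo].sum()
        cell_totals = mean[endo].sum(axis=0)
        mean[endo] *= target_total / cell_totals[None, :]
    mean = mean * np.where(spikein_mask[:, None], 1.0, lib[None, :])
    counts = _nb_sample(mean, config.dispersion, rng)

    matrix = StateCountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        state=np.array(state_labels),
        donor=np.array(donor_labels) if config.n_donors > 1 else None,
        spikein_mask=spikein_mask,
        states=tuple(config.states),
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "class": gene_class})
    return matrix, truth


# ---------------------------------------------------------------------------
# onset/censoring cohorts
# ---------------------------------------------------------------------------

def simulate_onset_cohort(
    n_per_group: Mapping[str, int],
    event_time_dists: Mapping[str, tuple],
    censor_time: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-group (or k-group) onset cohort.

    Each cell draws a latent onset time from its group's distribution; if
    the draw exceeds ``censor_time`` the cell is censored there (a cell
    that never secretes within the observation window).  Returns a
    DataFrame with columns ``cell_id``, ``group``, ``time_h``, ``event``.
    """
    if set(n_per_group) != set(event_time_dists):
        raise ConfigError("n_per_group and event_time_dists must share group names")
    if censor_time < 0:
        raise ConfigError(f"censor_time must be >= 0, got {censor_time}")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in n_per_group.items():
        if n < 1:
            raise ConfigError(f"group {group}: n must be >= 1, got {n}")
        latent = sample_dist(event_time_dists[group], n, rng)
        for i, t in enumerate(latent):
            event = t <= censor_time
            rows.append(
                (f"{group}_{i:04d}", group, float(min(t, censor_time)), bool(event))
            )
    return pd.DataFrame(rows, columns=["cell_id", "group", "time_h", "event"])
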