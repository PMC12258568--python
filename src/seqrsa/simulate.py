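"""Synthetic multivoxel data with planted, parameterized coding structure.

The generative model plants up to five kinds of coding into an ROI's voxel
patterns, each as an independent standard-normal latent pattern per item:

* key patterns (one per finger), object patterns (one per object),
* position patterns (one per stream position 1-8),
* item-position patterns (one per learned ordinal slot, present only in the
  sequence conditions; shared between domains when ``domain_general``),
* a single boundary pattern added at stream positions 1 and 8.

A regressor's simulated t-map is the mean of its five events' signals plus
per-regressor Gaussian noise; between-subject variability is additive
Gaussian jitter on the latent patterns.  By default the simulator enters
the pipeline at the t-map level; :func:`simulate_bold` provides the slower
voxel-time-series front end for the GLM stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from .glm import hrf_convolve_impulses, relabel_events
from .protocol import SubjectProtocol
from .tmaps import OBJECT_INDEX, SCHEMES, TMapSet

N_ITEMS = 8
EVENTS_PER_REGRESSOR = 5


@dataclass(frozen=True)
class CodingAmplitudes:
    """Effect amplitudes of the planted coding, in units of pattern SD.

    The defaults describe a moderate-SNR regime: item effects comparable to
    the per-regressor noise after averaging five events, with weaker
    position/boundary structure — the regime in which recovery is possible
    but not trivial.  ``domain_general`` shares one set of item-position
    patterns between the motor and object domains.
    """

    a_itempos: float = 0.5
    a_key: float = 0.7
    a_obj: float = 0.4
    a_pos: float = 0.5
    a_boundary: float = 0.4
    domain_general: bool = True
    noise_sigma: float = 1.0
    subject_sigma: float = 0.25

    def __post_init__(self) -> None:
        for name in ("a_itempos", "a_key", "a_obj", "a_pos", "a_boundary",
                     "subject_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")

    def null(self) -> "CodingAmplitudes":
        """Copy with every amplitude set to zero (noise retained)."""
        return replace(self, a_itempos=0.0, a_key=0.0, a_obj=0.0,
                       a_pos=0.0, a_boundary=0.0)


@dataclass
class PatternBank:
    """Latent voxel patterns for one ROI (before subject jitter)."""

    pos: np.ndarray          # (8, V) position patterns
    key: np.ndarray          # (8, V) key patterns
    obj: np.ndarray          # (8, V) object patterns (canonical index order)
    slot_shared: np.ndarray  # (8, V) domain-general item-position patterns
    slot_mot: np.ndarray     # (8, V) motor-domain item-position patterns
    slot_obj: np.ndarray     # (8, V) object-domain item-position patterns
    boundary: np.ndarray     # (V,)
    n_voxels: int

    def jittered(self, subject_sigma: float,
                 rng: np.random.Generator) -> "PatternBank":
        """Subject-specific bank: additive Gaussian jitter on every pattern."""
        if subject_sigma == 0:
            return self

        def j(a):
            return a + subject_sigma * rng.standard_normal(a.shape)

        return PatternBank(
            pos=j(self.pos), key=j(self.key), obj=j(self.obj),
            slot_shared=j(self.slot_shared), slot_mot=j(self.slot_mot),
            slot_obj=j(self.slot_obj), boundary=j(self.boundary),
            n_voxels=self.n_voxels,
        )


def sample_pattern_bank(n_voxels: int, seed) -> PatternBank:
    """Draw independent standard-normal latent patterns for one ROI."""
    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2")
    rng = np.random.default_rng(seed)
    shape = (N_ITEMS, n_voxels)
    return PatternBank(
        pos=rng.standard_normal(shape),
        key=rng.standard_normal(shape),
        obj=rng.standard_normal(shape),
        slot_shared=rng.standard_normal(shape),
        slot_mot=rng.standard_normal(shape),
        slot_obj=rng.standard_normal(shape),
        boundary=rng.standard_normal(n_voxels),
        n_voxels=n_voxels,
    )


def _events_frame(protocol) -> pd.DataFrame:
    if isinstance(protocol, SubjectProtocol):
        return protocol.events
    return protocol


def _event_signals(events: pd.DataFrame, bank: PatternBank,
                   amps: CodingAmplitudes) -> np.ndarray:
    """Deterministic signal component of every event, (n_events, V)."""
    pos = events["position"].to_numpy() - 1
    key = events["key"].to_numpy() - 1
    obj = events["object"].map(OBJECT_INDEX).to_numpy() - 1
    cond = events["condition"].to_numpy()
    E = (amps.a_key * bank.key[key]
         + amps.a_obj * bank.obj[obj]
         + amps.a_pos * bank.pos[pos])
    is_boundary = (pos == 0) | (pos == N_ITEMS - 1)
    E[is_boundary] += amps.a_boundary * bank.boundary
    # item-position patterns, sequence conditions only, indexed by slot
    slot_mot = bank.slot_shared if amps.domain_general else bank.slot_mot
    slot_obj = bank.slot_shared if amps.domain_general else bank.slot_obj
    m = cond == "SQ_MOT"
    E[m] += amps.a_itempos * slot_mot[pos[m]]
    m = cond == "SQ_OBJ"
    E[m] += amps.a_itempos * slot_obj[pos[m]]
    return E


class TmapSimulator:
    """Reusable t-map simulator bound to one subject's event table.

    Precomputes the event-to-regressor grouping for all three schemes so a
    cohort-level simulation can re-draw noise cheaply for many subjects or
    replications of the same protocol.
    """

    def __init__(self, protocol) -> None:
        events = _events_frame(protocol)
        self.events = events.reset_index(drop=True)
        self.groups: list[tuple[tuple, np.ndarray]] = []
        for scheme in SCHEMES:
            labeled = relabel_events(self.events, scheme)
            grouped = labeled.groupby(["run", "condition", "label"]).indices
            for (run, condition, label), idx in sorted(grouped.items()):
                self.groups.append(
                    ((int(run), scheme, condition, int(label)), np.asarray(idx))
                )
        # all groups hold exactly EVENTS_PER_REGRESSOR events, so the group
        # means collapse into one gather over a (n_groups, 5) index matrix
        self._group_keys = [k for k, _ in self.groups]
        self._group_idx = np.stack([idx for _, idx in self.groups])

    def simulate(self, bank: PatternBank, amps: CodingAmplitudes,
                 rng: np.random.Generator) -> TMapSet:
        subject_bank = bank.jittered(amps.subject_sigma, rng)
        E = _event_signals(self.events, subject_bank, amps)
        V = bank.n_voxels
        G = E[self._group_idx].mean(axis=1)
        G += amps.noise_sigma * rng.standard_normal((len(self._group_keys), V))
        data = dict(zip(self._group_keys, G))
        return TMapSet(data=data, n_voxels=V, normalized=False)


def simulate_tmaps(protocol, bank: PatternBank, amps: CodingAmplitudes,
                   seed) -> TMapSet:
    """Simulate one subject's per-regressor t-maps directly.

    Each regressor vector is the mean of its events' planted signals (under
    the subject-jittered bank) plus run-level Gaussian regressor noise.
    """
    rng = np.random.default_rng(seed)
    return TmapSimulator(protocol).simulate(bank, amps, rng)


# ---------------------------------------------------------------------------
# optional BOLD-level front end
# ---------------------------------------------------------------------------

def simulate_bold(
    protocol,
    bank: PatternBank,
    amps: CodingAmplitudes,
    tr: float,
    seed,
    drift_amplitude: float = 0.0,
    n_scans: dict[int, int] | None = None,
) -> dict[int, np.ndarray]:
    """Voxel time series per run: HRF-convolved impulses + drift + noise.

    Event amplitudes per voxel are the same planted signals consumed by
    :func:`simulate_tmaps`; impulses at cue onsets are convolved with the
    canonical double-gamma HRF on the same oversampled grid the GLM stage
    uses for its design columns, so a noiseless simulation lies exactly in
    the GLM's model class.  ``noise_sigma`` acts as the white-noise SD of
    the scan-level series.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    rng = np.random.default_rng(seed)
    events = _events_frame(protocol)
    subject_bank = bank.jittered(amps.subject_sigma, rng)
    V = bank.n_voxels
    out: dict[int, np.ndarray] = {}
    for run, run_events in events.groupby("run"):
        E = _event_signals(run_events, subject_bank, amps)
        last = run_events.iloc[-1]
        if n_scans and run in n_scans:
            ns = n_scans[run]
        else:
            ns = int(np.ceil((last["onset_s"] + last["isi_s"] + 24.0) / tr))
        series = hrf_convolve_impulses(
            run_events["onset_s"].to_numpy(), E, tr, ns)
        if drift_amplitude > 0:
            t = np.arange(ns) * tr
            basis = np.stack([np.cos(2 * np.pi * t / p) for p in (256.0, 384.0)])
            series = series + drift_amplitude * (
                rng.standard_normal((2, V)).T @ basis
            ).T
        series = series + amps.noise_sigma * rng.standard_normal((ns, V))
        out[int(run)] = series
    return out


# ---------------------------------------------------------------------------
# behavioral responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters for trial-level responses.

    RT decays exponentially with practiced blocks from ``baseline_rt_s``
    toward ``asymptote_rt_s``; sequence conditions are faster than random
    by ``sequence_advantage_s`` in expectation; errors are i.i.d. Bernoulli.
    """

    baseline_rt_s: float = 0.9
    asymptote_rt_s: float = 0.45
    learning_rate: float = 0.02
    sequence_advantage_s: float = 0.08
    rt_sigma_s: float = 0.15
    error_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_rt_s <= 0:
            raise ValueError("baseline_rt_s must be positive")
        if not 0 <= self.asymptote_rt_s <= self.baseline_rt_s:
            raise ValueError("asymptote_rt_s must be in [0, baseline_rt_s]")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")


def simulate_behavior(protocol, params: BehaviorParams, seed) -> pd.DataFrame:
    """Attach RT (s) and correctness to every trial of an events table.

    Accepts a :class:`~seqrsa.protocol.SubjectProtocol` (scanner events) or
    any events DataFrame with ``subject``, ``condition`` and ``block``
    columns (e.g. the behavioral sessions).
    """
    rng = np.random.default_rng(seed)
    events = _events_frame(protocol).copy().reset_index(drop=True)
    group_cols = [c for c in ("session", "run", "block") if c in events.columns]
    block_key = events[["subject", *group_cols]].astype(str).agg("|".join, axis=1)
    practice_index = (block_key != block_key.shift()).groupby(
        events["subject"]).cumsum()
    is_seq = events["condition"].isin(["SQ_MOT", "SQ_OBJ"]).to_numpy()
    mean_rt = (
        params.asymptote_rt_s
        + (params.baseline_rt_s - params.asymptote_rt_s)
        * np.exp(-params.learning_rate * (practice_index - 1))
        - params.sequence_advantage_s * is_seq
    )
    rt = mean_rt + params.rt_sigma_s * rng.standard_normal(len(events))
    events["rt_s"] = np.clip(rt, 0.05, None)
    events["correct"] = rng.random(len(events)) >= params.error_rate
    return events
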