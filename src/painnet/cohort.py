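"""Synthetic resting-state cohorts with a planted pain-network structure.

Emulates the study design the pipeline targets: two diagnostic groups
(``patient``, ``control``), patients scanned in two medication sessions
(``ON``, ``OFF``), controls once.  Each subject-session yields a regional
time-series matrix drawn from a zero-mean multivariate normal whose target
correlation is ``baseline_r`` between all node pairs and an elevated value
within a designated pain-network block, a six-parameter motion trace
(smooth AR(1) drift plus occasional translation spikes), and pain scores.

The clinical pain outcome (NWC, number of words chosen on the McGill pain
questionnaire) is planted on the *generating* pain-network topology:

    nwc = round(max(0, beta_pain * GE_true + noise)),

where ``GE_true`` is the global efficiency of the noise-free generating
pain-block network (a complete uniform graph with Fisher-z weight
arctanh(r)).  Between-subject variation of the pain-block correlation
(``pain_r_sd``) makes the planted association recoverable by the regression
stage.  Everything is deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from . import topology
from .connectivity import fisher_transform
from .types import MOTION_COLUMNS, MotionTrace, RoiTimeSeries

GROUPS = ("patient", "control")

#: AR(1) motion drift: coefficient and innovation SDs (mm for translations,
#: degrees for rotations, stored in radians).
MOTION_AR_COEF = 0.95
MOTION_INNOVATION_SD_MM = 0.02
MOTION_INNOVATION_SD_DEG = 0.02

#: Chronic-pain prevalence used for the boolean metadata column, by group.
CHRONIC_PAIN_P = MappingProxyType({"patient": 0.75, "control": 0.407})
#: Exponential-scale means for the two 0-100 colored-analogue-scale ratings.
CAS_SCALE = MappingProxyType(
    {"patient": (16.0, 16.0), "control": (4.3, 2.8)}
)


@dataclass(frozen=True)
class CohortDesign:
    """Generating parameters for a synthetic cohort.

    Defaults mirror the target study: 24 patients (two sessions each) and 27
    controls (one session), 264 atlas nodes, 199 analyzed frames per scan.
    ``pain_r_by_group`` sets the group-level pain-block correlation;
    ``pain_r_sd`` the between-subject spread around it.  ``beta_pain`` links
    NWC to the true pain-network global efficiency (pain-score units per GE
    unit); ``beta_pain = 0`` gives a null cohort.  ``link_target="bc"``
    plants the pain-score link on mean pain-network z-BC of the noise-free
    generating graph instead of GE.
    """

    n_patients: int = 24
    n_controls: int = 27
    n_nodes: int = 264
    n_frames: int = 199
    baseline_r: float = 0.10
    pain_r_by_group: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType({"patient": 0.45, "control": 0.30})
    )
    pain_r_sd: float = 0.10
    noise_sd: float = 0.5
    motion_spike_prob: float = 0.02
    motion_spike_mm: float = 2.0
    beta_pain: float = 40.0
    pain_noise_sd: float = 2.0
    seed: int = 0
    pain_nodes: tuple[int, ...] | None = None
    link_target: str = "ge"

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or self.n_frames < 3:
            raise ValueError("need n_nodes >= 2 and n_frames >= 3")
        if not 0 <= self.baseline_r < 1:
            raise ValueError("baseline_r must be in [0, 1)")
        for g, r in self.pain_r_by_group.items():
            if not 0 <= r < 1:
                raise ValueError(f"pain_r_by_group[{g!r}] must be in [0, 1)")
        if self.link_target not in ("ge", "bc"):
            raise ValueError("link_target must be 'ge' or 'bc'")
        if self.pain_nodes is not None:
            if len(set(self.pain_nodes)) != len(self.pain_nodes):
                raise ValueError("pain_nodes has duplicates")
            if any(i < 0 or i >= self.n_nodes for i in self.pain_nodes):
                raise ValueError("pain_nodes outside [0, n_nodes)")

    def resolved_pain_nodes(self) -> tuple[int, ...]:
        """Pain-block indices: explicit, else the packaged pain set (264-node
        designs), else the first 16 nodes (or all, if fewer)."""
        if self.pain_nodes is not None:
            return tuple(self.pain_nodes)
        if self.n_nodes == 264:
            from .nodesets import load_nodeset

            return load_nodeset("pain").indices
        return tuple(range(min(16, self.n_nodes)))


@dataclass
class SubjectRecord:
    """One subject-session: signals, motion, pain scores, metadata."""

    subject_id: str
    group: str
    session: str
    time_series: RoiTimeSeries
    motion: MotionTrace
    cas_intensity: float
    cas_affect: float
    nwc: int
    chronic_pain: bool

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.motion.n_frames != self.time_series.n_frames:
            raise ValueError("motion and time series frame counts differ")
        if not 0 <= self.cas_intensity <= 100 or not 0 <= self.cas_affect <= 100:
            raise ValueError("CAS scores must lie in [0, 100]")
        if self.nwc < 0 or self.nwc != int(self.nwc):
            raise ValueError("nwc must be a non-negative integer")
        self.nwc = int(self.nwc)


def target_correlation(
    design: CohortDesign, pain_r: float
) -> np.ndarray:
    """Target node-by-node correlation: baseline everywhere, ``pain_r`` within
    the pain block.  Verified positive semi-definite; rejected otherwise with
    the offending parameters named."""
    n = design.n_nodes
    c = np.full((n, n), design.baseline_r)
    idx = np.asarray(design.resolved_pain_nodes(), dtype=int)
    c[np.ix_(idx, idx)] = pain_r
    np.fill_diagonal(c, 1.0)
    eigmin = float(np.linalg.eigvalsh(c).min())
    if eigmin < -1e-10:
        raise ValueError(
            "target covariance is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3e}) for baseline_r={design.baseline_r}, "
            f"pain_r={pain_r}, n_nodes={n}"
        )
    return c


def _correlation_factor(c: np.ndarray) -> np.ndarray:
    """A factor A with A @ A.T = c, tolerant of semi-definite targets."""
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(c)
        return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _true_pain_topology(design: CohortDesign, pain_r: float) -> float:
    """Planted topology value of the noise-free generating network.

    ``link_target="ge"``: GE of the pain block in isolation (complete uniform
    Fisher-z graph, so GE = arctanh(pain_r), but computed through the real
    graph code).  ``link_target="bc"``: mean z-scored whole-graph BC over the
    pain nodes of the full generating correlation network.
    """
    if design.link_target == "ge":
        k = len(design.resolved_pain_nodes())
        block = np.full((k, k), pain_r)
        np.fill_diagonal(block, 1.0)
        adj = fisher_transform(block)
        return topology.global_efficiency(adj)
    adj = fisher_transform(target_correlation(design, pain_r))
    z = topology.zscore_bc(topology.betweenness_centrality(adj))
    idx = np.asarray(design.resolved_pain_nodes(), dtype=int)
    return float(z[idx].mean())


def _simulate_session(
    design: CohortDesign, pain_r: float, rng: np.random.Generator
) -> tuple[RoiTimeSeries, MotionTrace]:
    """One session's time series and motion trace."""
    c = target_correlation(design, pain_r)
    a = _correlation_factor(c)
    signal = rng.standard_normal((design.n_frames, design.n_nodes)) @ a.T
    if design.noise_sd > 0:
        signal = signal + rng.normal(
            0.0, design.noise_sd, size=signal.shape
        )
    labels = tuple(f"node{i:03d}" for i in range(design.n_nodes))
    ts = RoiTimeSeries(signal, labels)

    innov_sd = np.array(
        [MOTION_INNOVATION_SD_MM] * 3
        + [np.deg2rad(MOTION_INNOVATION_SD_DEG)] * 3
    )
    steps = rng.normal(0.0, 1.0, size=(design.n_frames, 6)) * innov_sd
    m = np.zeros((design.n_frames, 6))
    for t in range(1, design.n_frames):
        m[t] = MOTION_AR_COEF * m[t - 1] + steps[t]
    if design.motion_spike_prob > 0:
        spikes = rng.random(design.n_frames) < design.motion_spike_prob
        axes = rng.integers(0, 3, size=design.n_frames)
        signs = rng.choice([-1.0, 1.0], size=design.n_frames)
        for t in np.flatnonzero(spikes):
            m[t, axes[t]] += signs[t] * design.motion_spike_mm
    return ts, MotionTrace(m)


def _subject_scores(
    design: CohortDesign, group: str, rng: np.random.Generator
) -> tuple[float, int, bool]:
    """Subject-level draws: pain-block correlation, NWC, chronic-pain flag."""
    base = design.pain_r_by_group[group]
    pain_r = float(np.clip(rng.normal(base, design.pain_r_sd), 0.0, 0.9))
    true_topo = _true_pain_topology(design, pain_r)
    nwc = int(
        round(
            max(
                0.0,
                design.beta_pain * true_topo
                + rng.normal(0.0, design.pain_noise_sd),
            )
        )
    )
    chronic = bool(rng.random() < CHRONIC_PAIN_P[group])
    return pain_r, nwc, chronic


def _session_cas(
    design: CohortDesign, group: str, rng: np.random.Generator
) -> tuple[float, float]:
    s_int, s_aff = CAS_SCALE[group]
    cas_i = float(np.clip(rng.exponential(s_int), 0.0, 100.0))
    cas_a = float(np.clip(rng.exponential(s_aff), 0.0, 100.0))
    return round(cas_i, 1), round(cas_a, 1)


def simulate_subject(
    design: CohortDesign,
    group: str,
    seed: int,
    *,
    subject_id: str | None = None,
    session: str | None = None,
) -> SubjectRecord:
    """Simulate a single subject-session, deterministic given ``seed``.

    ``session`` defaults to ``"OFF"`` for patients and ``"single"`` for
    controls.
    """
    if group not in design.pain_r_by_group:
        raise ValueError(f"group {group!r} is not a key of pain_r_by_group")
    rng = np.random.default_rng(seed)
    pain_r, nwc, chronic = _subject_scores(design, group, rng)
    cas_i, cas_a = _session_cas(design, group, rng)
    ts, motion = _simulate_session(design, pain_r, rng)
    return SubjectRecord(
        subject_id=subject_id or f"{group[:3]}{seed:04d}",
        group=group,
        session=session or ("OFF" if group == "patient" else "single"),
        time_series=ts,
        motion=motion,
        cas_intensity=cas_i,
        cas_affect=cas_a,
        nwc=nwc,
        chronic_pain=chronic,
    )


def simulate_cohort(
    design: CohortDesign,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Simulate the full cohort: patients twice (ON, OFF), controls once.

    Within a patient, the two sessions share the subject-level pain-block
    correlation, NWC and chronic-pain flag (the questionnaire is answered
    once) but have independent scan realizations and session-specific CAS
    ratings.  Returns the subject-session records and the cohort table
    (one row per subject-session).
    """
    if design.n_patients < 2 or design.n_controls < 2:
        raise ValueError(
            "need at least 2 subjects per group; downstream statistics are "
            "undefined otherwise"
        )
    ss = np.random.SeedSequence(design.seed)
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in ss.spawn(design.n_patients + design.n_controls)
    ]
    records: list[SubjectRecord] = []
    k = 0
    for i in range(design.n_patients):
        rng = np.random.default_rng(child_seeds[k])
        k += 1
        sid = f"pat{i + 1:03d}"
        pain_r, nwc, chronic = _subject_scores(design, "patient", rng)
        for session in ("ON", "OFF"):
            cas_i, cas_a = _session_cas(design, "patient", rng)
            ts, motion = _simulate_session(design, pain_r, rng)
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group="patient",
                    session=session,
                    time_series=ts,
                    motion=motion,
                    cas_intensity=cas_i,
                    cas_affect=cas_a,
                    nwc=nwc,
                    chronic_pain=chronic,
                )
            )
    for i in range(design.n_controls):
        rng = np.random.default_rng(child_seeds[k])
        k += 1
        sid = f"con{i + 1:03d}"
        pain_r, nwc, chronic = _subject_scores(design, "control", rng)
        cas_i, cas_a = _session_cas(design, "control", rng)
        ts, motion = _simulate_session(design, pain_r, rng)
        records.append(
            SubjectRecord(
                subject_id=sid,
                group="control",
                session="single",
                time_series=ts,
                motion=motion,
                cas_intensity=cas_i,
                cas_affect=cas_a,
                nwc=nwc,
                chronic_pain=chronic,
            )
        )
    table = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "session": [r.session for r in records],
            "cas_intensity": [r.cas_intensity for r in records],
            "cas_affect": [r.cas_affect for r in records],
            "nwc": [r.nwc for r in records],
            "chronic_pain": [r.chronic_pain for r in records],
        }
    )
    return records, table


def null_design(design: CohortDesign) -> CohortDesign:
    """The same design with no planted group or pain-score effect."""
    r = design.pain_r_by_group.get("control", design.baseline_r)
    return replace(
        design,
        pain_r_by_group=MappingProxyType({g: r for g in design.pain_r_by_group}),
        beta_pain=0.0,
    )


def write_cohort(
    records: list[SubjectRecord], table: pd.DataFrame, outdir: str | Path
) -> Path:
    """Write per-session TSVs and the cohort table.

    Layout: ``<id>_<session>_timeseries.tsv`` (frames x nodes, header = node
    labels), ``<id>_<session>_motion.tsv`` (frames x 6, standard motion
    column names), ``cohort.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in records:
        stem = f"{r.subject_id}_{r.session}"
        pd.DataFrame(r.time_series.values, columns=list(r.time_series.node_labels)).to_csv(
            outdir / f"{stem}_timeseries.tsv", sep="\t", index=False
        )
        pd.DataFrame(r.motion.values, columns=list(MOTION_COLUMNS)).to_csv(
            outdir / f"{stem}_motion.tsv", sep="\t", index=False
        )
    table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    return outdir
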