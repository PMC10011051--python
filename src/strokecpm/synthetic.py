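"""Synthetic rs-fMRI cohorts with a planted edge-behavior structure.

Real post-stroke rs-fMRI cohorts of the kind this package analyses are not
publicly shareable, so every downstream stage is exercised on synthetic
cohorts with a recoverable ground truth.  The generative model:

* Each subject k carries one scalar latent recovery strength z_k ~ N(0, 1),
  shared by all planted edges — the simplest structure that makes the
  planted edges jointly informative.
* Planted edge (i, j) has connectivity  c_ij(k) = s * z_k + noise,  with
  loading s (``connectivity_scale``) and edge noise of sd
  ``base_connectivity_sd``; background edges are i.i.d. noise around 0.
* Behavior is linear in the latent on a standardized scale, then mapped to
  the measure's clinical scale:

      b_k = center + spread * (effect_size * z_k + eps),  eps ~ N(0, noise_sd)

  and discretized: mRS to integers clamped to [0, 6] (stage-1 cohorts are
  clamped to {2, 3, 4}, mirroring recruitment limited to moderate
  disability), BI to multiples of 5 in [0, 100].  Behavior defaults to a
  stage-2 score because predictive cells always regress a *later*-stage
  score on earlier connectivity.

The sign of ``effect_size`` sets the expected polarity of the planted
edges (positive -> pos-edges).

Two routes exist: :func:`generate_connectomes_direct` draws connectivity
values directly (fast, for statistical tests), and :func:`generate_cohort`
synthesises band-limited BOLD-like node time series whose correlation
structure realises the same targets (via Cholesky factoring of a per-subject
target correlation matrix), plus nuisance signals (six motion parameters,
global/WM/CSF proxies) and linear drift for the preprocessing stage to
remove.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .connectome import SubjectConnectome, edge_count, matrix_from_edges
from .cpm import BehaviorArray, EdgeMask
from .timeseries import SubjectTimeseries

__all__ = [
    "SyntheticSpec",
    "generate_cohort",
    "generate_connectomes_direct",
    "write_behavior",
    "write_ground_truth",
]

#: (center, spread, clamp range, rounding step) per measure; behavior is
#: center + spread * standardized-latent, so effect_size and noise_sd are in
#: standardized units for both measures.
_MEASURE_SCALE = {
    "mRS": (3.0, 1.0, (0.0, 6.0), 1.0),
    "BI": (60.0, 15.0, (0.0, 100.0), 5.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Defaults emulate the emulated study design: N = 38 subjects (the
    largest patient group), M = 116 nodes (AAL-style parcellation), T = 155
    retained volumes at TR = 2 s, five planted edges.
    """

    n_subjects: int = 38
    n_nodes: int = 116
    n_timepoints: int = 155
    tr_seconds: float = 2.0
    planted_edges: tuple[tuple[int, int], ...] | None = None
    n_planted: int = 5
    effect_size: float = 1.0
    noise_sd: float = 0.5
    measure: Literal["mRS", "BI"] = "mRS"
    stage: int = 2
    base_connectivity_sd: float = 0.3
    connectivity_scale: float = 0.3
    discretize: bool = True
    restrict_stage1_mrs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if self.n_timepoints < 20:
            raise ValueError("need at least 20 time points")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.base_connectivity_sd <= 0:
            # zero is allowed only for noiseless toy checks
            if self.base_connectivity_sd < 0:
                raise ValueError("base_connectivity_sd must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.measure not in _MEASURE_SCALE:
            raise ValueError(f"unknown measure: {self.measure!r}")
        if self.planted_edges is not None:
            edges = tuple(tuple(e) for e in self.planted_edges)
            if len(edges) < 1:
                raise ValueError("need at least one planted edge")
            for i, j in edges:
                if not (0 <= i < j < self.n_nodes):
                    raise ValueError(
                        f"planted edge ({i}, {j}) must satisfy 0 <= i < j < M"
                    )
            if len(set(edges)) != len(edges):
                raise ValueError("planted edges must be unique")
            object.__setattr__(self, "planted_edges", edges)
        elif self.n_planted < 1:
            raise ValueError("need at least one planted edge")

    @property
    def polarity(self) -> str:
        """Expected polarity of the planted edges."""
        return "neg" if self.effect_size < 0 else "pos"

    def resolve_edges(self, rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
        if self.planted_edges is not None:
            return self.planted_edges
        idx = rng.choice(edge_count(self.n_nodes), size=self.n_planted,
                         replace=False)
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return tuple(sorted((int(iu[e]), int(ju[e])) for e in np.sort(idx)))


def _behavior_from_latent(spec: SyntheticSpec, z: np.ndarray,
                          rng: np.random.Generator) -> BehaviorArray:
    center, spread, (lo, hi), step = _MEASURE_SCALE[spec.measure]
    if spec.measure == "mRS" and spec.stage == 1 and spec.restrict_stage1_mrs:
        lo, hi = 2.0, 4.0
    raw = center + spread * (spec.effect_size * z
                             + rng.normal(0.0, spec.noise_sd, z.size))
    raw = np.clip(raw, lo, hi)
    if spec.discretize:
        raw = np.clip(np.round(raw / step) * step, lo, hi)
    ids = [f"sub-{k:03d}" for k in range(z.size)]
    return BehaviorArray(subject_ids=ids, scores=raw, measure=spec.measure,
                         stage=spec.stage)


def _ground_truth(spec: SyntheticSpec,
                  edges: tuple[tuple[int, int], ...]) -> EdgeMask:
    mask = np.zeros((spec.n_nodes, spec.n_nodes))
    for i, j in edges:
        mask[i, j] = mask[j, i] = 1
    return EdgeMask(mask=mask, polarity=spec.polarity, alpha=1.0)


def generate_connectomes_direct(
    spec: SyntheticSpec,
) -> tuple[list[SubjectConnectome], BehaviorArray, EdgeMask]:
    """Draw connectivity matrices directly (no time-series stage).

    Planted edges follow the latent; background edges are i.i.d. around 0
    with sd ``base_connectivity_sd``.  Matrices are symmetric with zero
    diagonal and entries clipped to valid correlation range.
    """
    rng = np.random.default_rng(spec.seed)
    edges = spec.resolve_edges(rng)
    n, m = spec.n_subjects, spec.n_nodes
    z = rng.standard_normal(n)

    values = rng.normal(0.0, spec.base_connectivity_sd, (n, edge_count(m)))
    iu, ju = np.triu_indices(m, k=1)
    edge_index = {(int(i), int(j)): e for e, (i, j) in enumerate(zip(iu, ju))}
    for i, j in edges:
        values[:, edge_index[(i, j)]] += spec.connectivity_scale * z
    values = np.clip(values, -0.999, 0.999)

    mats = matrix_from_edges(values, m)
    connectomes = [
        SubjectConnectome(subject_id=f"sub-{k:03d}", matrix=mats[k])
        for k in range(n)
    ]
    behavior = _behavior_from_latent(spec, z, rng)
    return connectomes, behavior, _ground_truth(spec, edges)


def _nearest_correlation(target: np.ndarray) -> np.ndarray:
    """Clip eigenvalues to keep the target matrix a valid correlation matrix."""
    vals, vecs = np.linalg.eigh(target)
    if vals.min() > 1e-8:
        return target
    vals = np.clip(vals, 1e-6, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _band_limit(data: np.ndarray, tr: float, low: float, high: float) -> np.ndarray:
    t = data.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr)
    spectrum = np.fft.rfft(data, axis=0)
    spectrum[(freqs < low) | (freqs > high), :] = 0.0
    return np.fft.irfft(spectrum, n=t, axis=0)


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[list[SubjectTimeseries], BehaviorArray, EdgeMask]:
    """Synthesise BOLD-like node time series realising the planted structure.

    Per subject, a target correlation matrix (identity plus the planted-edge
    correlations for that subject) is Cholesky-factored and applied to white
    Gaussian noise; the mixed signals are then band-limited to roughly the
    resting-state band, contaminated with nuisance signals (slow motion
    random walks plus global/WM/CSF proxies) and per-node linear drift.
    Running the preprocessing chain and Pearson connectivity on the output
    recovers the planted correlations up to sampling noise.
    """
    rng = np.random.default_rng(spec.seed)
    edges = spec.resolve_edges(rng)
    n, m, t = spec.n_subjects, spec.n_nodes, spec.n_timepoints
    z = rng.standard_normal(n)

    subjects: list[SubjectTimeseries] = []
    for k in range(n):
        target = np.eye(m)
        for i, j in edges:
            rho = spec.connectivity_scale * z[k] + rng.normal(
                0.0, spec.base_connectivity_sd)
            rho = float(np.clip(rho, -0.9, 0.9))
            target[i, j] = target[j, i] = rho
        target = _nearest_correlation(target)
        chol = np.linalg.cholesky(target)

        white = rng.standard_normal((t, m))
        signal = white @ chol.T
        # keep a band slightly wider than the analysis passband so the
        # 0.01-0.08 Hz filter leaves the planted structure intact
        signal = _band_limit(signal, spec.tr_seconds, 0.005, 0.1)
        signal /= max(signal.std(), 1e-12)

        # nuisance design: 6 slow motion random walks + 3 signal proxies
        motion = np.cumsum(rng.normal(0.0, 0.05, (t, 6)), axis=0)
        proxies = _band_limit(rng.standard_normal((t, 3)), spec.tr_seconds,
                              0.0, 0.1)
        nuisance = np.column_stack([motion, proxies])

        loadings = rng.normal(0.0, 0.3, (9, m))
        drift = np.outer(np.linspace(-1, 1, t), rng.normal(0.0, 0.5, m))
        data = signal + nuisance @ loadings + drift
        subjects.append(SubjectTimeseries(subject_id=f"sub-{k:03d}",
                                          data=data, nuisance=nuisance))

    behavior = _behavior_from_latent(spec, z, rng)
    return subjects, behavior, _ground_truth(spec, edges)


def write_behavior(behavior: BehaviorArray, path: str | Path,
                   group: str = "SYN") -> None:
    """Behavior table CSV: subject_id, group, stage, measure, score."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "stage", "measure", "score"])
        for sid, score in zip(behavior.subject_ids, behavior.scores):
            writer.writerow([sid, group, behavior.stage, behavior.measure,
                             f"{score:g}"])


def write_ground_truth(mask: EdgeMask, path: str | Path) -> None:
    """Planted-edge list as two-column 0-based text (i, j with i < j)."""
    with open(path, "w") as fh:
        for i, j in mask.edges():
            fh.write(f"{i}\t{j}\n")


# --------------------------------------------------------------------------
# Full multi-group study synthesis


@dataclass(frozen=True)
class GroupDesign:
    """Design of one synthetic patient group within a study.

    ``effect_size`` links the latent to behavior only for
    ``effect_measure`` ("mRS", "BI" or "both"); with ``effect_prediction``
    set (e.g. ``(1, 2)``), the latent enters only the stage-1 connectomes
    and the stage-2 behavior, so exactly that prediction cell carries
    signal.  With it unset, every stage shares the latent.
    """

    name: str
    n_subjects: int
    effect_size: float = 0.0
    effect_measure: str | None = None
    effect_prediction: tuple[int, int] | None = None


#: group sizes emulating the study design (supratentorial, left/right
#: subgroups, brainstem)
DEFAULT_GROUPS = (
    GroupDesign("ST", 38), GroupDesign("ST.L", 26),
    GroupDesign("ST.R", 12), GroupDesign("BS", 17),
)

_STAGE_CENTERS = {"mRS": {1: 3.0, 2: 2.0, 3: 1.5},
                  "BI": {1: 60.0, 2: 80.0, 3: 90.0}}


def generate_study(seed: int = 0,
                   groups: tuple[GroupDesign, ...] = DEFAULT_GROUPS,
                   n_nodes: int = 116, n_planted: int = 5,
                   noise_sd: float = 0.5, base_connectivity_sd: float = 0.3,
                   connectivity_scale: float = 0.3,
                   trait_sd: float = 0.5):
    """Synthesise a full study: per-group, per-stage connectomes and scores.

    Every group gets its own latent recovery strength per subject and its
    own planted edges.  Behavior centers drift toward recovery across
    stages (mRS falls, BI rises); a per-subject trait (sd ``trait_sd``)
    couples a subject's scores across stages without touching connectivity.
    Returns a list of :class:`~strokecpm.study.CohortData`.
    """
    from .study import CohortData

    cohorts = []
    for g_idx, design in enumerate(groups):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, g_idx]))
        n = design.n_subjects
        z = rng.standard_normal(n)
        trait = rng.normal(0.0, trait_sd, n)
        ids = [f"{design.name}-{k:03d}" for k in range(n)]

        spec = SyntheticSpec(n_subjects=n, n_nodes=n_nodes,
                             n_planted=n_planted,
                             base_connectivity_sd=base_connectivity_sd,
                             connectivity_scale=connectivity_scale,
                             seed=0)
        edges = spec.resolve_edges(rng)
        iu, ju = np.triu_indices(n_nodes, k=1)
        edge_index = {(int(i), int(j)): e for e, (i, j) in enumerate(zip(iu, ju))}

        connectomes: dict[int, list[SubjectConnectome]] = {}
        for stage in (1, 2, 3):
            values = rng.normal(0.0, base_connectivity_sd,
                                (n, edge_count(n_nodes)))
            source = (design.effect_prediction is None
                      or stage == design.effect_prediction[0])
            if design.effect_size != 0.0 and source:
                for i, j in edges:
                    values[:, edge_index[(i, j)]] += connectivity_scale * z
            mats = matrix_from_edges(np.clip(values, -0.999, 0.999), n_nodes)
            connectomes[stage] = [
                SubjectConnectome(subject_id=ids[k], matrix=mats[k])
                for k in range(n)
            ]

        behaviors: dict[tuple[str, int], BehaviorArray] = {}
        for measure in ("mRS", "BI"):
            _, spread, (lo, hi), step = _MEASURE_SCALE[measure]
            for stage in (1, 2, 3):
                target = (design.effect_prediction is None
                          or stage == design.effect_prediction[1])
                linked = (design.effect_measure in (measure, "both")
                          and design.effect_size != 0.0 and target)
                effect = design.effect_size if linked else 0.0
                center = _STAGE_CENTERS[measure][stage]
                raw = center + spread * (effect * z + trait
                                         + rng.normal(0.0, noise_sd, n))
                s_lo, s_hi = lo, hi
                if measure == "mRS" and stage == 1:
                    s_lo, s_hi = 2.0, 4.0
                raw = np.clip(np.round(np.clip(raw, s_lo, s_hi) / step) * step,
                              s_lo, s_hi)
                behaviors[(measure, stage)] = BehaviorArray(
                    subject_ids=ids, scores=raw, measure=measure, stage=stage)

        cohorts.append(CohortData(name=design.name, connectomes=connectomes,
                                  behaviors=behaviors))
    return cohorts


def write_study(cohorts, out_dir: str | Path, config_name: str = "study.yaml",
                **config_extras) -> Path:
    """Write a synthetic study to disk in the layout the study runner reads.

    Produces, per group, one behavior CSV plus one directory of M x M
    connectivity matrices per stage, and a YAML study config referencing
    them.  Returns the config path.
    """
    from .connectome import write_matrix
    import yaml as _yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    group_entries = []
    for cohort in cohorts:
        gdir = out_dir / cohort.name.replace(".", "_")
        gdir.mkdir(exist_ok=True)
        rows = []
        for (measure, stage), beh in sorted(cohort.behaviors.items()):
            for sid, score in zip(beh.subject_ids, beh.scores):
                rows.append((sid, cohort.name, stage, measure, f"{score:g}"))
        with open(gdir / "behavior.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject_id", "group", "stage", "measure", "score"])
            writer.writerows(rows)
        conn_dirs = {}
        for stage, conns in sorted(cohort.connectomes.items()):
            sdir = gdir / f"stage{stage}"
            sdir.mkdir(exist_ok=True)
            for conn in conns:
                write_matrix(conn.matrix, sdir / f"{conn.subject_id}.txt")
            conn_dirs[stage] = str(sdir.relative_to(out_dir))
        group_entries.append({
            "name": cohort.name,
            "behavior": str((gdir / "behavior.csv").relative_to(out_dir)),
            "connectomes": conn_dirs,
        })
    config = {"groups": group_entries, **config_extras}
    config_path = out_dir / config_name
    config_path.write_text(_yaml.safe_dump(config, sort_keys=False))
    return config_path
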