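"""Batch orchestration of the full study grid.

The emulated design evaluates CPM over the Cartesian product of patient
groups x assessment measures (mRS, BI) x stage-pair predictions (1->2,
1->3, 2->3) x edge polarities (pos, neg) — 4 x 2 x 3 x 2 = 48 model cells
in the full design.  Every cell runs LOOCV; cells passing the significance
rule additionally get a permutation test and consensus brain-net export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .atlas import Atlas, aal116
from .brainnet import edge_consensus, top_k_consensus, write_brainnet
from .connectome import SubjectConnectome, read_matrix
from .cpm import BehaviorArray
from .validation import classify_significance, loocv, permutation_test

logger = logging.getLogger(__name__)

__all__ = [
    "CohortData",
    "StudyConfig",
    "ModelCell",
    "enumerate_cells",
    "run_study",
    "summarize_scores",
    "load_study_config",
]

PREDICTIONS = ((1, 2), (1, 3), (2, 3))


@dataclass
class CohortData:
    """One patient group: per-stage connectomes and per-(measure, stage) scores."""

    name: str
    connectomes: dict[int, list[SubjectConnectome]]
    behaviors: dict[tuple[str, int], BehaviorArray]

    @property
    def n_subjects(self) -> int:
        return len(next(iter(self.connectomes.values())))


@dataclass
class StudyConfig:
    groups: list[CohortData]
    measures: Sequence[str] = ("mRS", "BI")
    predictions: Sequence[tuple[int, int]] = PREDICTIONS
    polarities: Sequence[str] = ("pos", "neg")
    edge_alpha: float = 0.05
    p_threshold: float = 0.05
    n_perm: int = 10_000
    perm_all: bool = False
    consensus_threshold: float = 0.9
    top_edges: int | None = None
    n_minus_one: bool = False
    seed: int = 0
    output_dir: Path | None = None
    atlas: Atlas | None = None

    def __post_init__(self) -> None:
        for i, j in self.predictions:
            if not i < j:
                raise ValueError(
                    f"prediction {i}->{j} must map an earlier stage to a later one"
                )


@dataclass(frozen=True)
class ModelCell:
    group: str
    measure: str
    prediction: tuple[int, int]
    polarity: str

    @property
    def label(self) -> str:
        i, j = self.prediction
        return f"{self.group}_{self.measure}_{i}to{j}_{self.polarity}"


def enumerate_cells(config: StudyConfig) -> list[ModelCell]:
    """Deterministic Cartesian product of the study dimensions."""
    dims = {
        "groups": [g.name for g in config.groups],
        "measures": list(config.measures),
        "predictions": [tuple(p) for p in config.predictions],
        "polarities": list(config.polarities),
    }
    for name, values in dims.items():
        if not values:
            raise ValueError(f"study dimension {name!r} is empty")
    return [
        ModelCell(group=g, measure=m, prediction=p, polarity=pol)
        for g, m, p, pol in product(dims["groups"], dims["measures"],
                                    dims["predictions"], dims["polarities"])
    ]


def _cell_seed(base_seed: int, index: int) -> int:
    # stable per-cell stream, independent of which cells are permuted
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0]
               % (2 ** 31))


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run LOOCV over every model cell; permutation-test the significant ones.

    Returns the machine twin of the study's correlation table: one row per
    cell with (R, p), the permutation p where computed, and the
    significance flag.  Deterministic given (config, seed).  Per-cell
    failures are logged and marked, not fatal.  When ``output_dir`` is set,
    writes ``results.csv``, per-significant-cell scatter data and BrainNet
    consensus files.
    """
    cells = enumerate_cells(config)
    groups = {g.name: g for g in config.groups}
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    n_cells = len(cells)
    logger.info("running %d model cells (edge alpha %.3g, %d permutations); "
                "p-values are reported raw, uncorrected across cells",
                n_cells, config.edge_alpha, config.n_perm)

    rows = []
    for index, cell in enumerate(cells):
        group = groups[cell.group]
        stage_conn, stage_beh = cell.prediction
        record = {
            "group": cell.group, "measure": cell.measure,
            "prediction": f"{stage_conn}->{stage_beh}",
            "polarity": cell.polarity,
            "R": np.nan, "p": np.nan, "perm_p": np.nan,
            "n_subjects": np.nan, "n_folds": np.nan,
            "significant": False, "status": "ok",
        }
        try:
            connectomes = group.connectomes[stage_conn]
            behavior = group.behaviors[(cell.measure, stage_beh)]
            if len(connectomes) != len(behavior):
                raise ValueError("connectome/behavior subject mismatch")
            cv = loocv(connectomes, behavior, alpha=config.edge_alpha,
                       polarity=cell.polarity,
                       n_minus_one=config.n_minus_one)
            record.update(R=cv.R, p=cv.p, n_subjects=len(behavior),
                          n_folds=cv.n_folds)
            significant = classify_significance(cv, config.p_threshold)
            record["significant"] = significant
            if not cv.valid:
                record["status"] = "invalid"

            if (significant or config.perm_all) and cv.valid:
                perm = permutation_test(
                    connectomes, behavior, alpha=config.edge_alpha,
                    polarity=cell.polarity, n_perm=config.n_perm,
                    seed=_cell_seed(config.seed, index))
                record["perm_p"] = perm.perm_p

            if significant and out_dir:
                _export_cell(cell, cv, group, config, out_dir)
        except Exception as exc:  # noqa: BLE001 - per-cell isolation
            logger.error("cell %s failed: %s", cell.label, exc)
            record["status"] = f"error: {exc}"
        rows.append(record)

    table = pd.DataFrame(rows)
    if out_dir:
        table.to_csv(out_dir / "results.csv", index=False,
                     float_format="%.6g")
    return table


def _export_cell(cell: ModelCell, cv, group: CohortData,
                 config: StudyConfig, out_dir: Path) -> None:
    scatter = pd.DataFrame({"true": cv.true_scores,
                            "predicted": cv.predicted_scores})
    scatter.to_csv(out_dir / f"scatter_{cell.label}.csv", index=False,
                   float_format="%.6g")
    n_nodes = cv.fold_masks[0].n_nodes if cv.fold_masks else 0
    atlas = config.atlas
    if atlas is None:
        atlas = aal116() if n_nodes == 116 else _generic_atlas(n_nodes)
    if config.top_edges is not None:
        consensus = top_k_consensus(cv.fold_masks, k=config.top_edges,
                                    atlas=atlas)
    else:
        consensus = edge_consensus(cv.fold_masks,
                                   threshold=config.consensus_threshold,
                                   atlas=atlas)
    write_brainnet(consensus, out_dir / f"{cell.label}.node",
                   out_dir / f"{cell.label}.edge")


def _generic_atlas(n_nodes: int) -> Atlas:
    atlas = Atlas.generic(n_nodes)
    rng = np.random.default_rng(n_nodes)
    atlas.coordinates = np.round(rng.uniform(-70, 70, (n_nodes, 3)), 2)
    return atlas


def summarize_scores(scores: pd.DataFrame,
                     stage_pairs: Sequence[tuple[int, int]] = PREDICTIONS
                     ) -> pd.DataFrame:
    """Stage-to-stage comparison of assessment scores (convenience summary).

    ``scores`` must have columns subject_id, measure, stage, score.  For
    each measure and stage pair, reports the per-stage median (with
    quartiles) and the two-sided Wilcoxon signed-rank p-value over paired
    subjects; zero differences are dropped (the classic convention), and a
    pair with no nonzero differences is reported as p = 1.  A standard
    paired test for ordinal scores — descriptive reporting, not part of the
    predictive procedure.
    """
    required = {"subject_id", "measure", "stage", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")

    rows = []
    for measure, df_m in scores.groupby("measure", sort=True):
        wide = df_m.pivot_table(index="subject_id", columns="stage",
                                values="score")
        for s1, s2 in stage_pairs:
            if s1 not in wide.columns or s2 not in wide.columns:
                continue
            paired = wide[[s1, s2]].dropna()
            dropped = len(wide) - len(paired)
            if dropped:
                logger.warning("%s stages %d vs %d: dropped %d unpaired subjects",
                               measure, s1, s2, dropped)
            a, b = paired[s1].to_numpy(), paired[s2].to_numpy()
            diff = b - a
            if np.all(diff == 0):
                p_value = 1.0
            else:
                p_value = float(stats.wilcoxon(a, b, zero_method="wilcox",
                                               alternative="two-sided").pvalue)
            rows.append({
                "measure": measure, "stage_a": s1, "stage_b": s2,
                "n_paired": len(paired),
                "median_a": float(np.median(a)),
                "q1_a": float(np.percentile(a, 25)),
                "q3_a": float(np.percentile(a, 75)),
                "median_b": float(np.median(b)),
                "q1_b": float(np.percentile(b, 25)),
                "q3_b": float(np.percentile(b, 75)),
                "wilcoxon_p": p_value,
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Config-file loading (YAML)


def _load_group(entry: dict, base: Path) -> CohortData:
    name = entry["name"]
    behavior_csv = base / entry["behavior"]
    table = pd.read_csv(behavior_csv)
    behaviors: dict[tuple[str, int], BehaviorArray] = {}
    subject_ids = list(dict.fromkeys(table["subject_id"].astype(str)))
    for (measure, stage), df in table.groupby(["measure", "stage"]):
        df = df.set_index(df["subject_id"].astype(str))
        scores = [float(df.loc[sid, "score"]) for sid in subject_ids]
        behaviors[(str(measure), int(stage))] = BehaviorArray(
            subject_ids=subject_ids, scores=np.asarray(scores),
            measure=str(measure), stage=int(stage))
    connectomes: dict[int, list[SubjectConnectome]] = {}
    for stage, dirname in entry["connectomes"].items():
        stage_dir = base / dirname
        connectomes[int(stage)] = [
            SubjectConnectome(subject_id=sid,
                              matrix=read_matrix(stage_dir / f"{sid}.txt"))
            for sid in subject_ids
        ]
    return CohortData(name=name, connectomes=connectomes, behaviors=behaviors)


def load_study_config(path: str | Path, **overrides) -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML file.

    Paths inside the file are resolved relative to its directory.  Keyword
    overrides (e.g. ``seed=...``, ``n_perm=...``) take precedence over the
    file's values.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent
    groups = [_load_group(g, base) for g in raw["groups"]]
    kwargs: dict = {"groups": groups}
    for key in ("measures", "polarities", "edge_alpha", "p_threshold",
                "n_perm", "perm_all", "consensus_threshold", "top_edges",
                "n_minus_one", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "predictions" in raw:
        kwargs["predictions"] = [
            tuple(int(s) for s in str(p).replace("->", " ").split())
            for p in raw["predictions"]
        ]
    if "output_dir" in raw:
        kwargs["output_dir"] = base / raw["output_dir"]
    kwargs.update(overrides)
    return StudyConfig(**kwargs)
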