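"""Gradient-boosted binary classification of AS events (proteomics-detected
vs transcript-only) with stratified cross-validation and permutation
importance.

The reference hyperparameters target an XGBoost-style booster; the backend
is pluggable and falls back to scikit-learn's GradientBoostingClassifier,
mapping the parameters it supports (learning rate, depth, subsample,
minimum child weight) and emulating scale_pos_weight through sample
weights.  The quantity of interest is the feature ranking, not a weights
artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .digest import DigestParams, digest, get_protease
from .splicing import ASEvent

__all__ = [
    "ModelConfig",
    "FEATURE_COLUMNS",
    "featurize",
    "train_eval",
    "CVResult",
    "permutation_importance",
]

PROTEASE_ORDER = ("aspn", "chymotrypsin", "gluc", "lysc", "lysn", "trypsin")

FEATURE_COLUMNS = (
    "log_abundance",
    "psi",
    "exon_len",
    "cds_len",
    "frame_preserving",
    *(f"min_cov_{p}" for p in PROTEASE_ORDER),
)


@dataclass(frozen=True)
class ModelConfig:
    learning_rate: float = 0.05
    reg_alpha: float = 1.15  # L1
    reg_lambda: float = 4.0  # L2
    min_child_weight: float = 2.0
    max_depth: int = 3
    gamma: float = 2.0
    colsample_bytree: float = 0.3
    subsample: float = 0.65
    scale_pos_weight: float = 4.44
    n_estimators: int = 200
    folds: int = 7
    importance_shuffles: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.importance_shuffles < 1:
            raise ValueError("importance_shuffles must be >= 1")


def _make_model(cfg: ModelConfig):
    try:  # pragma: no cover - exercised only where xgboost is installed
        from xgboost import XGBClassifier

        return XGBClassifier(
            learning_rate=cfg.learning_rate,
            reg_alpha=cfg.reg_alpha,
            reg_lambda=cfg.reg_lambda,
            min_child_weight=cfg.min_child_weight,
            max_depth=cfg.max_depth,
            gamma=cfg.gamma,
            colsample_bytree=cfg.colsample_bytree,
            subsample=cfg.subsample,
            scale_pos_weight=cfg.scale_pos_weight,
            n_estimators=cfg.n_estimators,
            random_state=cfg.seed,
            eval_metric="logloss",
        )
    except ImportError:
        from sklearn.ensemble import GradientBoostingClassifier

        return GradientBoostingClassifier(
            learning_rate=cfg.learning_rate,
            max_depth=cfg.max_depth,
            subsample=cfg.subsample,
            min_samples_leaf=max(int(cfg.min_child_weight), 1),
            n_estimators=cfg.n_estimators,
            random_state=cfg.seed,
        )


def _sample_weight(y: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    w = np.ones(len(y), dtype=float)
    w[y == 1] = cfg.scale_pos_weight
    return w


def min_theoretical_junction_coverage(
    protein_by_path: Sequence[str],
    junction_aa_by_path: Sequence[Sequence[int]],
    protease: str,
    window_aa: int = 35,
    params: DigestParams = DigestParams(),
) -> float:
    """Minimum over event paths of the coverable fraction of
    junction-proximal residues (within ``window_aa`` of a junction) by
    fully-specific retained peptides of one protease."""
    rule = get_protease(protease)
    fractions = []
    for protein, junction_positions in zip(protein_by_path, junction_aa_by_path):
        if not protein or not junction_positions:
            fractions.append(0.0)
            continue
        region = np.zeros(len(protein), dtype=bool)
        for aa_pos in junction_positions:  # 1-based
            lo = max(0, aa_pos - 1 - window_aa)
            hi = min(len(protein), aa_pos - 1 + window_aa)
            region[lo:hi] = True
        covered = np.zeros(len(protein), dtype=bool)
        for rec in digest(protein, rule, params):
            covered[rec.start : rec.end] = True
        denom = int(region.sum())
        fractions.append(float((covered & region).sum() / denom) if denom else 0.0)
    return min(fractions) if fractions else 0.0


def featurize(
    events: Sequence[ASEvent],
    event_meta: pd.DataFrame,
    proteins_by_event: Mapping[int, Sequence[str]],
    junctions_by_event: Mapping[int, Sequence[Sequence[int]]],
    window_aa: int = 35,
) -> pd.DataFrame:
    """EventFeatures table.

    ``event_meta`` must align with ``events`` and carry ``abundance``,
    ``psi``, ``exon_len``, ``cds_len`` columns; events without RNA support
    (abundance <= 0 or null psi) are excluded with a count column in
    ``attrs``.
    """
    rows = []
    n_excluded = 0
    for i, ev in enumerate(events):
        meta = event_meta.iloc[i]
        if meta["abundance"] <= 0 or pd.isna(meta["psi"]):
            n_excluded += 1
            continue
        row = {
            "event_index": i,
            "log_abundance": float(np.log2(meta["abundance"])),
            "psi": float(meta["psi"]),
            "exon_len": float(meta["exon_len"]),
            "cds_len": float(meta["cds_len"]),
            "frame_preserving": int(ev.frame_preserving),
        }
        for p in PROTEASE_ORDER:
            row[f"min_cov_{p}"] = min_theoretical_junction_coverage(
                proteins_by_event[i], junctions_by_event[i], p, window_aa
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = n_excluded
    if len(df) and df[list(FEATURE_COLUMNS)].isna().any().any():
        raise ValueError("featurization produced missing values")
    return df


def synthetic_event_dataset(
    result,
    evidence: pd.DataFrame,
    min_flank: int = 3,
    window_aa: int = 35,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Features and detection labels for every cassette event of a
    synthetic dataset (see module synth).

    The label is True when any of the event's three junctions (two
    inclusion, one exclusion) is crossed by an evidence peptide with the
    required flank: proteomics-detected vs transcript-only.
    """
    from collections import namedtuple

    from .splicing import junction_peptide_support, project_peptide

    Stub = namedtuple("EventStub", ["frame_preserving"])
    events, meta_rows, proteins_by_event, junctions_by_event, labels = [], [], {}, {}, []
    for gene in result.genes:
        tids = set(gene.isoforms)
        sub = evidence[evidence["protein_id"].isin(tids)]
        alignments = [
            project_peptide(gene, r["protein_id"], int(r["start"]), int(r["end"]),
                            r["sequence"])
            for _, r in sub.iterrows()
        ]
        support = junction_peptide_support(alignments, min_flank=min_flank)
        for truth_ev in result.truth.events:
            if truth_ev.gene_id != gene.gene_id:
                continue
            incl_tid, skip_tid = truth_ev.inclusion_isoform, truth_ev.skip_isoform
            exon_ids = gene.isoforms[incl_tid]
            cassette_idx = exon_ids.index(truth_ev.cassette_exon)
            incl_junctions = gene.junctions(incl_tid)
            flanking = [incl_junctions[cassette_idx - 1], incl_junctions[cassette_idx]]
            skip_junctions = gene.junctions(skip_tid)
            excl = skip_junctions[cassette_idx - 1]
            detected = any(
                len(support.get(j, ())) > 0 for j in [*flanking, excl]
            )
            # junction aa positions within each path's protein
            def aa_positions(tid, junctions):
                out = []
                blocks = gene.exon_blocks(tid)
                acc = 0
                spans = []
                for s, e in blocks:
                    spans.append((acc, acc + e - s + 1))
                    acc += e - s + 1
                for j in junctions:
                    # junction sits at the boundary after some exon
                    for (s, e), (cs, ce) in zip(blocks, spans):
                        donor = e if gene.strand == "+" else s
                        if donor == j[0]:
                            out.append(ce // 3 + 1)
                            break
                return out

            i = len(events)
            events.append(Stub(truth_ev.frame_preserving))
            meta_rows.append(
                {
                    "abundance": result.truth.gene_abundance[gene.gene_id],
                    "psi": truth_ev.psi,
                    "exon_len": truth_ev.exon_len,
                    "cds_len": 3 * len(result.truth.proteins[incl_tid]),
                }
            )
            proteins_by_event[i] = [
                result.truth.proteins[incl_tid],
                result.truth.proteins[skip_tid],
            ]
            junctions_by_event[i] = [
                aa_positions(incl_tid, flanking),
                aa_positions(skip_tid, [excl]),
            ]
            labels.append(detected)
    meta = pd.DataFrame(meta_rows)
    features = featurize(events, meta, proteins_by_event, junctions_by_event, window_aa)
    kept = features["event_index"].to_numpy()
    return features, np.asarray(labels, dtype=int)[kept]


@dataclass
class CVResult:
    auc_per_fold: list[float]
    auc_pooled: float
    roc_curves: list[tuple[np.ndarray, np.ndarray]]
    oof_scores: np.ndarray
    models: list = field(default_factory=list)
    fold_indices: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def train_eval(
    features: pd.DataFrame,
    labels: Sequence[int],
    cfg: ModelConfig = ModelConfig(),
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
) -> CVResult:
    """Stratified k-fold CV; per-fold ROC curves and pooled out-of-fold AUC."""
    X = features[list(feature_columns)].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    oof = np.zeros(len(y), dtype=float)
    aucs, curves, models, fold_indices = [], [], [], []
    for train_idx, val_idx in skf.split(X, y):
        model = _make_model(cfg)
        model.fit(X[train_idx], y[train_idx], sample_weight=_sample_weight(y[train_idx], cfg))
        scores = model.predict_proba(X[val_idx])[:, 1]
        oof[val_idx] = scores
        aucs.append(float(roc_auc_score(y[val_idx], scores)))
        fpr, tpr, _ = roc_curve(y[val_idx], scores)
        curves.append((fpr, tpr))
        models.append(model)
        fold_indices.append((train_idx, val_idx))
    return CVResult(
        auc_per_fold=aucs,
        auc_pooled=float(roc_auc_score(y, oof)),
        roc_curves=curves,
        oof_scores=oof,
        models=models,
        fold_indices=fold_indices,
    )


def permutation_importance(
    model,
    features: pd.DataFrame,
    labels: Sequence[int],
    cfg: ModelConfig = ModelConfig(),
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
) -> pd.DataFrame:
    """Mean +- sd AUC drop per feature over ``cfg.importance_shuffles``
    column permutations, deterministic given ``cfg.seed``."""
    X = features[list(feature_columns)].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(cfg.seed)
    base_auc = float(roc_auc_score(y, model.predict_proba(X)[:, 1]))
    rows = []
    for j, col in enumerate(feature_columns):
        drops = np.empty(cfg.importance_shuffles)
        for s in range(cfg.importance_shuffles):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(y)), j]
            drops[s] = base_auc - float(roc_auc_score(y, model.predict_proba(Xp)[:, 1]))
        rows.append(
            {
                "feature": col,
                "importance_mean": float(drops.mean()),
                "importance_sd": float(drops.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows).sort_values(
        "importance_mean", ascending=False, ignore_index=True
    )
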