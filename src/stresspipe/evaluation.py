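"""Cross-validation protocols and the full study harness.

Two protocols estimate how well the stress classes can be recognised:

* leave-one-day-out (LODO), per user: each labeled day is classified by a
  model trained on the user's remaining days — the user-specific setting;
* leave-one-participant-out (LOPO): each user's days are classified by a
  model trained on everyone else — the general-model setting.

:func:`run_study` chains day alignment (smartphone days are kept only where
an HRV night exists), pooled correlation reduction, per-user sequential
selection, and both protocols for the three models M_P (phone features
only), M_H (HRV only) and M (all features), emitting a machine-readable
report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .hrv import HRV_FEATURES
from .model import DegenerateFitWarning, StressLogit
from .phone import PHONE_FEATURES
from .scores import map_score_to_class
from .selection import correlation_reduce, sequential_forward_select
from .types import ValidationError

__all__ = [
    "CVResult",
    "leave_one_day_out_cv",
    "leave_one_participant_out_cv",
    "run_study",
]

MODEL_TAGS = ("M_P", "M_H", "M")


@dataclass
class CVResult:
    """Accuracy of one model under one protocol."""

    model_tag: str
    protocol: str  # "LODO" | "LOPO"
    n_folds: int
    accuracy: float
    per_fold_outcomes: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model_tag": self.model_tag,
            "protocol": self.protocol,
            "n_folds": self.n_folds,
            "accuracy": self.accuracy,
            "per_fold_outcomes": self.per_fold_outcomes,
        }


def _clean(rows: pd.DataFrame, features: list[str], label_col: str) -> pd.DataFrame:
    return rows[features + [label_col]].dropna()


def leave_one_day_out_cv(
    user_rows: pd.DataFrame,
    features: list[str],
    label_col: str = "stress_class",
    ridge: float = 1e-4,
    model_tag: str = "M",
) -> CVResult:
    """Leave-one-day-out accuracy for a single user.

    One fold per labeled day; the held-out day is classified by a model
    trained on the other days. Folds whose training labels miss a class are
    still evaluated (that class is simply unreachable) and flagged in the
    per-fold outcomes.
    """
    sub = _clean(user_rows, features, label_col).reset_index(drop=True)
    n = len(sub)
    if n < 3:
        raise ValidationError(f"need at least 3 labeled days, got {n}")
    X = sub[features].to_numpy(float)
    y = sub[label_col].to_numpy(int)
    outcomes = []
    correct = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateFitWarning)
            res = StressLogit(y[mask], X[mask], feature_names=features, ridge=ridge).fit()
        pred = int(res.classify(X[i]) [0])
        hit = pred == y[i]
        correct += hit
        outcomes.append(
            {
                "fold": i,
                "true": int(y[i]),
                "predicted": pred,
                "correct": bool(hit),
                "train_missing_class": len(res.classes_present) < 3,
            }
        )
    return CVResult(model_tag, "LODO", n, correct / n, outcomes)


def leave_one_participant_out_cv(
    all_rows: pd.DataFrame,
    features: list[str],
    label_col: str = "stress_class",
    ridge: float = 1e-4,
    model_tag: str = "M",
) -> CVResult:
    """Leave-one-participant-out accuracy of the general model.

    One fold per user; accuracy is pooled over all held-out days."""
    sub = _clean(all_rows, features + ["subject_id"], label_col)
    users = sorted(sub["subject_id"].unique())
    if len(users) < 3:
        raise ValidationError(f"need at least 3 users, got {len(users)}")
    correct = 0
    total = 0
    outcomes = []
    for u in users:
        train = sub[sub["subject_id"] != u]
        test = sub[sub["subject_id"] == u]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateFitWarning)
            res = StressLogit(
                train[label_col].to_numpy(int),
                train[features],
                feature_names=features,
                ridge=ridge,
            ).fit()
        preds = res.classify(test[features])
        hits = int(np.sum(preds == test[label_col].to_numpy(int)))
        correct += hits
        total += len(test)
        outcomes.append(
            {
                "user": u,
                "n_days": int(len(test)),
                "n_correct": hits,
                "train_missing_class": len(res.classes_present) < 3,
            }
        )
    return CVResult(model_tag, "LOPO", len(users), correct / total, outcomes)


def _modality_features(tag: str, phone: list[str], hrv: list[str]) -> list[str]:
    return {"M_P": phone, "M_H": hrv, "M": phone + hrv}[tag]


def run_study(dataset: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Full evaluation: reduction, selection, and both CV protocols.

    ``dataset`` has one row per subject-day with columns ``subject_id``,
    ``date``, the 19 phone features, the 14 HRV features and
    ``stress_score``. Days without an HRV night (all HRV features missing)
    are excluded everywhere, mirroring the day-alignment rule of the study
    design. User-specific models are evaluated only for users with at least
    ``config.min_nights`` labeled nights.
    """
    cfg = config or PipelineConfig()
    df = dataset.copy()
    hrv_cols = [c for c in HRV_FEATURES if c in df.columns]
    phone_cols = [c for c in PHONE_FEATURES if c in df.columns]
    if not hrv_cols or not phone_cols or "stress_score" not in df.columns:
        raise ValidationError("dataset must carry phone features, HRV features and stress_score")
    # day alignment: drop days with no HRV recording
    has_hrv = df[hrv_cols].notna().any(axis=1)
    df = df[has_hrv].reset_index(drop=True)
    df["stress_class"] = [
        map_score_to_class(s, cfg.low_threshold, cfg.high_threshold)
        for s in df["stress_score"]
    ]

    # pooled correlation reduction, per modality
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        red_p = correlation_reduce(df[phone_cols], cfg.r_threshold, cfg.p_threshold)
        red_h = correlation_reduce(df[hrv_cols], cfg.r_threshold, cfg.p_threshold)
    phone_kept, hrv_kept = red_p.kept, red_h.kept

    report: dict = {
        "config": cfg.to_dict(),
        "n_users": int(df["subject_id"].nunique()),
        "n_days": int(len(df)),
        "reduction": {"phone": red_p.to_dict(), "hrv": red_h.to_dict()},
        "selection": {},
        "user_specific": {},
        "general": {},
        "warnings": [],
    }

    # --- user-specific: SFS + LODO per eligible user ---------------------
    eligible = [
        u
        for u, grp in df.groupby("subject_id")
        if grp[hrv_kept + ["stress_class"]].dropna().shape[0] >= cfg.min_nights
    ]
    selections: dict[str, dict[str, list[str]]] = {}
    per_user_acc: dict[str, dict[str, float]] = {tag: {} for tag in MODEL_TAGS}
    for u in sorted(eligible):
        grp = df[df["subject_id"] == u]
        selections[u] = {}
        for tag in MODEL_TAGS:
            cand = _modality_features(tag, phone_kept, hrv_kept)
            sub = grp[cand + ["stress_class"]].dropna()
            if sub.shape[0] < cfg.min_nights or sub["stress_class"].nunique() < 2:
                # degenerate user-model: selection impossible, use all candidates
                chosen = cand
            else:
                sel = sequential_forward_select(
                    sub[cand],
                    sub["stress_class"],
                    feature_names=cand,
                    folds=cfg.sfs_folds,
                    seed=cfg.seed,
                    min_improvement=cfg.min_improvement,
                    ridge=cfg.ridge,
                )
                chosen = sel.ordered_features or cand[:1]
            selections[u][tag] = chosen
            try:
                cv = leave_one_day_out_cv(
                    grp, chosen, ridge=cfg.ridge, model_tag=tag
                )
                per_user_acc[tag][u] = cv.accuracy
            except ValidationError as exc:
                report["warnings"].append(f"user {u} {tag}: {exc}")
    if eligible:
        report["user_specific"] = {
            tag: {
                "accuracy": float(np.mean(list(per_user_acc[tag].values())))
                if per_user_acc[tag]
                else None,
                "per_user": per_user_acc[tag],
                "protocol": "LODO",
            }
            for tag in MODEL_TAGS
        }
    else:
        report["warnings"].append(
            f"no user has >= {cfg.min_nights} labeled nights; "
            "user-specific section empty"
        )
    report["selection"]["per_user"] = selections

    # --- general model: aggregated subsets + LOPO ------------------------
    general_subsets: dict[str, list[str]] = {}
    for tag in MODEL_TAGS:
        cand = _modality_features(tag, phone_kept, hrv_kept)
        # order candidates by mean importance over the users that selected them
        gains: dict[str, list[float]] = {}
        for u in selections:
            sel = selections[u][tag]
            for rank, f in enumerate(sel):
                gains.setdefault(f, []).append(len(sel) - rank)
        if gains:
            ordered = sorted(
                gains, key=lambda f: (-float(np.mean(gains[f])), cand.index(f))
            )
        else:
            ordered = cand
        general_subsets[tag] = ordered
        try:
            cv = leave_one_participant_out_cv(
                df, ordered, ridge=cfg.ridge, model_tag=tag
            )
            report["general"][tag] = {
                "accuracy": cv.accuracy,
                "n_folds": cv.n_folds,
                "protocol": "LOPO",
            }
        except ValidationError as exc:
            report["warnings"].append(f"general {tag}: {exc}")
    report["selection"]["general"] = general_subsets
    return report
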