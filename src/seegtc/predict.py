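"""Two-level surgical-outcome prediction from pre-minus-post biomarker
deltas.

Sensor level: each non-thermocoagulated contact contributes one 8-feature
sample - (pre contact-mean minus post contact-mean) of line length and
approximate entropy in four bands - labelled positive if its patient is a
responder. The class imbalance (roughly 834 positive : 163 negative at the
emulated study's scale) is handled by partitioning the positive training
samples into five subsets of roughly negative-class size; an RBF
support-vector classifier is selected over (subset, hyperparameter) cells
by mean AUC under stratified 25-fold cross-validation.

Individual level: a patient's *response possibility* is the fraction of
their non-TC contacts the selected classifier marks positive; a patient is
predicted a responder when the possibility exceeds 0.5 (strict).

The modelling surface follows the statsmodels convention:
:class:`OutcomeModel` holds data and design choices; ``fit()`` returns an
:class:`OutcomeResults` carrying the selection grid, test-set metrics,
per-patient table and a ``summary()``.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .signal import BAND_ORDER

__all__ = [
    "SplitPlan",
    "DELTA_FEATURES",
    "build_delta_samples",
    "split_train_test",
    "subdivide_positives",
    "select_model",
    "evaluate_sensor_level",
    "response_possibility",
    "predict_individuals",
    "OutcomeModel",
    "OutcomeResults",
    "default_grid",
]

logger = logging.getLogger(__name__)

#: Canonical order of the eight delta features.
DELTA_FEATURES = tuple(
    f"{feat}_{band}" for feat in FEATURE_NAMES for band in BAND_ORDER
)

POSITIVE, NEGATIVE = 1, 0


@dataclass(frozen=True)
class SplitPlan:
    """Contact-level train/test split and positive-subset plan.

    test_fraction defaults to 1/6, matching 139/834 and 27/163 test
    proportions; subsets_k = 5 positive-class training subsets.
    """

    test_fraction: float = 1.0 / 6.0
    subsets_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.subsets_k < 1:
            raise ValueError("subsets_k must be >= 1")


def default_grid() -> list[dict]:
    """Hyperparameter grid: regularization C x RBF kernel scale gamma."""
    return [
        {"C": C, "gamma": gamma}
        for C in (0.1, 1.0, 10.0, 100.0)
        for gamma in ("scale", 0.01, 0.1, 1.0)
    ]


def build_delta_samples(
    contact_means: pd.DataFrame,
    contacts: pd.DataFrame,
    outcomes: pd.Series,
) -> pd.DataFrame:
    """One row per non-TC contact: the 8 pre-minus-post delta features and
    the inherited binary outcome label (1 = responder).

    Contacts missing either period are excluded with a warning; an error is
    raised if exclusions empty a class.
    """
    cm = contact_means.merge(
        contacts[["patient_id", "channel_name", "is_tc"]],
        on=["patient_id", "channel_name"], how="left",
    )
    cm = cm[~cm.is_tc.astype(bool)]
    wide = cm.pivot_table(
        index=["patient_id", "channel_name"],
        columns=["period", "band"], values=list(FEATURE_NAMES))
    rows = []
    for (pid, ch), row in wide.iterrows():
        vals = {}
        ok = True
        for feat in FEATURE_NAMES:
            for band in BAND_ORDER:
                try:
                    pre_v = row[(feat, "pre", band)]
                    post_v = row[(feat, "post", band)]
                except KeyError:
                    ok = False
                    break
                if pd.isna(pre_v) or pd.isna(post_v):
                    ok = False
                    break
                vals[f"{feat}_{band}"] = pre_v - post_v
            if not ok:
                break
        if not ok:
            logger.warning(
                "contact %s/%s lacks a period or band; excluded", pid, ch)
            continue
        rows.append({"patient_id": pid, "channel_name": ch, **vals,
                     "label": POSITIVE if outcomes[pid] == "responder"
                     else NEGATIVE})
    df = pd.DataFrame(rows, columns=["patient_id", "channel_name",
                                     *DELTA_FEATURES, "label"])
    if not df.empty and df.label.nunique() < outcomes.nunique():
        raise ValueError("delta-sample exclusions emptied an outcome class")
    return df


def split_train_test(
    samples: pd.DataFrame, plan: SplitPlan
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-stratified random split at ``plan.test_fraction`` (test size
    rounded to nearest per class); deterministic under ``plan.seed``."""
    if samples.label.nunique() < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(plan.seed)
    test_idx: list[int] = []
    for label, grp in samples.groupby("label"):
        if len(grp) < 2:
            raise ValueError(f"class {label} has < 2 samples")
        n_test = int(round(plan.test_fraction * len(grp)))
        n_test = min(max(n_test, 1), len(grp) - 1)
        chosen = rng.choice(grp.index.to_numpy(), size=n_test, replace=False)
        test_idx.extend(chosen.tolist())
    test_mask = samples.index.isin(test_idx)
    return samples[~test_mask].copy(), samples[test_mask].copy()


def subdivide_positives(
    train_positives: pd.DataFrame, k: int = 5, seed: int = 0
) -> list[pd.DataFrame]:
    """Random disjoint partition of the positive training samples into k
    near-equal subsets (sizes differ by at most 1, larger subsets first)."""
    if len(train_positives) < k:
        raise ValueError(
            f"cannot split {len(train_positives)} positives into {k} subsets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(train_positives.index.to_numpy())
    return [train_positives.loc[part].copy()
            for part in np.array_split(perm, k)]


def _make_svc(params: dict) -> SVC:
    return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])


def select_model(
    subsets: list[pd.DataFrame],
    train_negatives: pd.DataFrame,
    grid: list[dict] | None = None,
    folds: int = 25,
    seed: int = 0,
) -> dict:
    """Choose (positive subset, hyperparameters) by mean cross-validated AUC.

    Each positive subset is pooled with the full negative training set and
    scored by stratified ``folds``-fold CV of an RBF SVC's decision scores.
    Folds are reduced with a warning when a class is smaller than the fold
    count. Ties break to the smallest subset index, then the grid order
    (ascending C, then kernel scale as listed).

    Returns a dict with ``chosen_subset_index``, ``chosen_params``,
    ``cv_mean_auc``, a tidy ``grid_scores`` frame and the refitted
    ``model`` (chosen subset + negatives).
    """
    grid = default_grid() if grid is None else grid
    if not grid:
        raise ValueError("empty hyperparameter grid")
    records = []
    best = None  # (auc, subset_idx, grid_idx)
    for si, subset in enumerate(subsets):
        pool = pd.concat([subset, train_negatives])
        X = pool[list(DELTA_FEATURES)].to_numpy()
        y = pool.label.to_numpy()
        n_min = min(np.bincount(y).min(), len(y))
        n_folds = min(folds, int(n_min))
        if n_folds < folds:
            warnings.warn(
                f"reducing CV folds from {folds} to {n_folds} "
                f"(smallest class has {n_min} samples)", stacklevel=2)
        if n_folds < 2:
            raise ValueError("need >= 2 samples per class for CV")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed)
        fold_splits = list(skf.split(X, y))
        for gi, params in enumerate(grid):
            aucs = []
            for tr, va in fold_splits:
                if len(np.unique(y[va])) < 2:
                    continue  # AUC undefined on a single-class fold
                clf = _make_svc(params)
                clf.fit(X[tr], y[tr])
                aucs.append(roc_auc_score(y[va],
                                          clf.decision_function(X[va])))
            mean_auc = float(np.mean(aucs)) if aucs else float("nan")
            records.append({"subset": si, **{k: str(v) for k, v in
                                             params.items()},
                            "cv_mean_auc": mean_auc, "n_folds": n_folds})
            if np.isfinite(mean_auc) and (
                best is None or mean_auc > best[0] + 1e-12
            ):
                best = (mean_auc, si, gi)
    if best is None:
        raise ValueError("cross-validation produced no valid AUC")
    _, si, gi = best
    chosen_pool = pd.concat([subsets[si], train_negatives])
    model = _make_svc(grid[gi])
    model.fit(chosen_pool[list(DELTA_FEATURES)].to_numpy(),
              chosen_pool.label.to_numpy())
    return {
        "chosen_subset_index": si,
        "chosen_params": grid[gi],
        "cv_mean_auc": best[0],
        "grid_scores": pd.DataFrame(records),
        "model": model,
    }


def evaluate_sensor_level(model, test: pd.DataFrame) -> dict:
    """Accuracy, precision, recall, F1 at the classifier's default decision
    threshold, plus rank-statistic AUC from continuous decision scores, on
    the held-out test contacts. Responder is the positive class."""
    if test.empty:
        raise ValueError("empty test set")
    y = test.label.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined on a single-class test set")
    X = test[list(DELTA_FEATURES)].to_numpy()
    y_hat = model.predict(X)
    scores = model.decision_function(X)
    return {
        "accuracy": float(accuracy_score(y, y_hat)),
        "precision": float(precision_score(y, y_hat, pos_label=POSITIVE,
                                           zero_division=0)),
        "recall": float(recall_score(y, y_hat, pos_label=POSITIVE,
                                     zero_division=0)),
        "f1": float(f1_score(y, y_hat, pos_label=POSITIVE, zero_division=0)),
        "auc": float(roc_auc_score(y, scores)),
    }


def response_possibility(model, patient_samples: pd.DataFrame) -> float:
    """Fraction of one patient's non-TC contacts classified positive;
    computed over all of the patient's delta samples (train and test)."""
    if patient_samples.empty:
        raise ValueError("patient has no delta samples")
    y_hat = model.predict(patient_samples[list(DELTA_FEATURES)].to_numpy())
    return float(np.mean(y_hat == POSITIVE))


def apply_response_rule(possibility: float, threshold: float = 0.5) -> str:
    """The individual-level decision rule: responder iff the response
    possibility strictly exceeds the threshold ("over 50%")."""
    return "responder" if possibility > threshold else "non_responder"


def predict_individuals(
    model, samples: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-patient response possibility and predicted label.

    Strict inequality at the threshold: a possibility of exactly 0.5 is a
    non-responder ("over 50%" rule).
    """
    rows = []
    for pid, grp in samples.groupby("patient_id"):
        poss = response_possibility(model, grp)
        rows.append({
            "patient_id": pid,
            "n_contacts": len(grp),
            "response_possibility": poss,
            "predicted": apply_response_rule(poss, threshold),
        })
    return pd.DataFrame(rows)


@dataclass
class OutcomeModel:
    """Two-level outcome prediction model over contact delta samples.

    Parameters
    ----------
    samples : DataFrame
        Delta samples from :func:`build_delta_samples` (columns
        ``patient_id``, ``channel_name``, the 8 delta features, ``label``).
    plan : SplitPlan
    grid : list of dict, optional
        SVC hyperparameter grid; defaults to C in {0.1,1,10,100} x gamma in
        {scale, 0.01, 0.1, 1}.
    folds : int
        Cross-validation folds (reduced with a warning on small classes).
    """

    samples: pd.DataFrame
    plan: SplitPlan = field(default_factory=SplitPlan)
    grid: list[dict] | None = None
    folds: int = 25

    @classmethod
    def from_contact_means(
        cls,
        contact_means: pd.DataFrame,
        contacts: pd.DataFrame,
        outcomes: pd.Series,
        plan: SplitPlan | None = None,
        **kwargs,
    ) -> "OutcomeModel":
        samples = build_delta_samples(contact_means, contacts, outcomes)
        return cls(samples=samples, plan=plan or SplitPlan(), **kwargs)

    def fit(self, seed: int | None = None) -> "OutcomeResults":
        """Split, balance, select by CV AUC, refit, and evaluate both
        levels. Deterministic under (plan, seed)."""
        seed = self.plan.seed if seed is None else seed
        plan = SplitPlan(test_fraction=self.plan.test_fraction,
                         subsets_k=self.plan.subsets_k, seed=seed)
        train, test = split_train_test(self.samples, plan)
        subsets = subdivide_positives(
            train[train.label == POSITIVE], k=plan.subsets_k, seed=seed)
        negatives = train[train.label == NEGATIVE]
        selection = select_model(subsets, negatives, grid=self.grid,
                                 folds=self.folds, seed=seed)
        metrics = evaluate_sensor_level(selection["model"], test)
        patient_table = predict_individuals(selection["model"], self.samples)
        truth = self.samples.groupby("patient_id").label.first().map(
            {POSITIVE: "responder", NEGATIVE: "non_responder"})
        patient_table["outcome"] = patient_table.patient_id.map(truth)
        patient_table["correct"] = (
            patient_table.predicted == patient_table.outcome)
        return OutcomeResults(
            model=self, seed=seed, selection=selection,
            sensor_metrics=metrics, patient_table=patient_table,
            n_train=(int((train.label == POSITIVE).sum()),
                     int((train.label == NEGATIVE).sum())),
            n_test=(int((test.label == POSITIVE).sum()),
                    int((test.label == NEGATIVE).sum())),
        )


@dataclass
class OutcomeResults:
    """Fitted two-level predictor: selection grid, test-set metrics and
    per-patient predictions."""

    model: OutcomeModel
    seed: int
    selection: dict
    sensor_metrics: dict
    patient_table: pd.DataFrame
    n_train: tuple[int, int]
    n_test: tuple[int, int]

    @property
    def classifier(self):
        return self.selection["model"]

    @property
    def individual_accuracy(self) -> float:
        return float(self.patient_table.correct.mean())

    def summary(self) -> str:
        buf = io.StringIO()
        print("Two-level RF-TC outcome prediction", file=buf)
        print("=" * 54, file=buf)
        print(f"samples: {len(self.model.samples)} non-TC contacts "
              f"({int((self.model.samples.label == POSITIVE).sum())} pos / "
              f"{int((self.model.samples.label == NEGATIVE).sum())} neg)",
              file=buf)
        print(f"split:   train {self.n_train[0]}+/{self.n_train[1]}- | "
              f"test {self.n_test[0]}+/{self.n_test[1]}-  (seed {self.seed})",
              file=buf)
        sel = self.selection
        print(f"chosen:  subset {sel['chosen_subset_index']}, "
              f"params {sel['chosen_params']}, "
              f"CV mean AUC {sel['cv_mean_auc']:.3f}", file=buf)
        print("-" * 54, file=buf)
        print("sensor-level test metrics", file=buf)
        for k in ("accuracy", "precision", "recall", "f1", "auc"):
            print(f"  {k:<10s} {self.sensor_metrics[k]:.3f}", file=buf)
        print("-" * 54, file=buf)
        print("individual-level predictions (response possibility > 0.5)",
              file=buf)
        cols = ["patient_id", "outcome", "response_possibility", "predicted"]
        print(self.patient_table[cols].to_string(index=False,
                                                 float_format="%.3f"),
              file=buf)
        print(f"individual accuracy: {self.individual_accuracy:.2f}",
              file=buf)
        print("note: the train/test split is contact-level and ignores "
              "patient boundaries; response possibilities score training "
              "contacts too.", file=buf)
        return buf.getvalue()
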