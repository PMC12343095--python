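"""Splitting, training, early stopping and the metric suite.

Splits follow an 80:20 train/test partition by default, with an internal
validation carve-out for early stopping and optional 5-fold
cross-validation inside the training portion.  Three cold-start modes
probe generalisation to unseen entities:

* ``leave_combination_out`` — no unordered drug pair in the test set
  occurs in training;
* ``leave_drug_out`` — a sampled set of drugs is held out; every test
  record contains a held-out drug and no held-out drug occurs in any
  training pair;
* ``leave_cell_line_out`` — no test cell line occurs in training.

Training minimises mean-squared error (regression) or binary
cross-entropy (classification) with adaptive-moment gradient descent and
stops when the validation loss has not improved by at least ``tol`` for
30 consecutive epochs, or has strictly increased for 10 consecutive
epochs.  Repeated evaluation reruns split+training under independent
seeds (15 by default) and reports Student-t confidence intervals on the
mean of each metric.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import stats as sps
from sklearn import metrics as skm

from .model import ModelConfig, SynergyModel
from .nn import Adam

__all__ = [
    "SplitError",
    "SplitPlan",
    "TrainingHistory",
    "TrainConfig",
    "MetricsReport",
    "make_split",
    "leakage_audit",
    "early_stop_check",
    "train_model",
    "permute_labels",
    "compute_metrics",
    "evaluate_model",
    "repeat_evaluate",
    "tune_hyperparameters",
]

MODES = ("random", "kfold", "leave_combination_out", "leave_drug_out", "leave_cell_line_out")


class SplitError(ValueError):
    """Split-mode constraints cannot be satisfied on the given records."""


@dataclass
class SplitPlan:
    mode: str
    seed: int
    ratio: float
    k: int
    train_idx: list
    val_idx: list
    test_idx: list
    folds: list = field(default_factory=list)       # kfold: [(train, val), ...]
    held_out: list = field(default_factory=list)    # cold-start entities

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SplitPlan":
        d = json.loads(s)
        d["folds"] = [tuple(f) for f in d.get("folds", [])]
        return cls(**d)


def _carve_validation(train: np.ndarray, rng, val_fraction: float):
    train = np.array(train)
    rng.shuffle(train)
    n_val = max(1, int(round(val_fraction * len(train)))) if len(train) > 1 else 0
    return train[n_val:].tolist(), train[:n_val].tolist()


def make_split(records, mode: str = "random", ratio: float = 0.8, k: int = 5,
               seed: int = 0, val_fraction: float = 0.1,
               holdout_fraction: float = 0.2) -> SplitPlan:
    """Build a train/validation/test split plan over record indices.

    Cold-start modes hold out a sampled ``holdout_fraction`` of the
    mode's entity (drug pairs, drugs, or cell lines); validation is
    carved from the training records for early stopping.
    """
    if not records:
        raise SplitError("cannot split an empty record list")
    if mode not in MODES:
        raise SplitError(f"unknown split mode {mode!r}; expected one of {MODES}")
    rng = np.random.default_rng(seed)
    n = len(records)
    idx = np.arange(n)
    held = []

    if mode in ("random", "kfold"):
        rng.shuffle(idx)
        n_train = int(round(ratio * n))
        train_pool, test = idx[:n_train], idx[n_train:]
    else:
        if mode == "leave_combination_out":
            entities = sorted({records[i].pair_key for i in idx})
            belongs = lambda r, held_set: r.pair_key in held_set
        elif mode == "leave_drug_out":
            entities = sorted({d for r in records for d in (r.drug_a_id, r.drug_b_id)})
            belongs = lambda r, held_set: (r.drug_a_id in held_set or r.drug_b_id in held_set)
        else:  # leave_cell_line_out
            entities = sorted({r.cell_line_id for r in records})
            belongs = lambda r, held_set: r.cell_line_id in held_set
        if len(entities) < 2:
            raise SplitError(f"{mode} needs >= 2 distinct entities, got {len(entities)}")
        n_held = max(1, int(round(holdout_fraction * len(entities))))
        if n_held >= len(entities):
            n_held = len(entities) - 1
        held = [entities[i] for i in rng.choice(len(entities), size=n_held, replace=False)]
        held_set = set(held)
        test = np.array([i for i in idx if belongs(records[i], held_set)])
        train_pool = np.array([i for i in idx if not belongs(records[i], held_set)])
        if len(test) == 0 or len(train_pool) == 0:
            raise SplitError(f"{mode}: holdout left an empty train or test set")
        # validation honours the same cold-start constraint: held-out
        # validation entities, so early stopping sees the same kind of
        # distribution shift the test set poses.  Among a few candidate
        # draws, keep the one whose validation label mix best matches the
        # training pool: a near-single-class validation set makes the
        # early-stopping signal meaningless (uses training labels only).
        remaining = [e for e in entities if e not in held_set]
        n_val_ent = max(1, int(round(val_fraction * len(remaining))))
        if n_val_ent >= len(remaining):
            n_val_ent = len(remaining) - 1
        pool_mean = float(np.mean([records[i].label for i in train_pool]))
        best_choice, best_score = None, np.inf
        for _ in range(20):
            cand = {remaining[i] for i in
                    rng.choice(len(remaining), size=n_val_ent, replace=False)}
            cand_val = [i for i in train_pool if belongs(records[i], cand)]
            if not cand_val or len(cand_val) == len(train_pool):
                continue
            score = abs(float(np.mean([records[i].label for i in cand_val])) - pool_mean)
            if score < best_score:
                best_choice, best_score = cand, score
        if best_choice is None:
            # degenerate pools (every record shares the remaining entities):
            # fall back to a record-level validation carve-out
            train, val = _carve_validation(train_pool, rng, val_fraction)
        else:
            val = [i for i in train_pool if belongs(records[i], best_choice)]
            train = [i for i in train_pool if not belongs(records[i], best_choice)]
        held_serializable = [list(h) if isinstance(h, tuple) else h for h in held]
        return SplitPlan(mode=mode, seed=seed, ratio=ratio, k=k,
                         train_idx=list(map(int, train)), val_idx=list(map(int, val)),
                         test_idx=list(map(int, test)), folds=[],
                         held_out=held_serializable)

    folds = []
    if mode == "kfold":
        pool = np.array(train_pool)
        rng.shuffle(pool)
        parts = np.array_split(pool, k)
        for j in range(k):
            val = parts[j]
            tr = np.concatenate([parts[m] for m in range(k) if m != j])
            folds.append((tr.tolist(), val.tolist()))
        train, val = folds[0]
    else:
        train, val = _carve_validation(train_pool, rng, val_fraction)

    held_serializable = [list(h) if isinstance(h, tuple) else h for h in held]
    return SplitPlan(mode=mode, seed=seed, ratio=ratio, k=k,
                     train_idx=list(map(int, train)), val_idx=list(map(int, val)),
                     test_idx=list(map(int, test)), folds=folds,
                     held_out=held_serializable)


def leakage_audit(plan: SplitPlan, records) -> dict:
    """Programmatic checks of the split invariants; all values must be True."""
    train = [records[i] for i in plan.train_idx + plan.val_idx]
    test = [records[i] for i in plan.test_idx]
    used = set(plan.train_idx) | set(plan.val_idx) | set(plan.test_idx)
    audit = {
        "disjoint": len(plan.train_idx) + len(plan.val_idx) + len(plan.test_idx) == len(used),
        "covers_records": used == set(range(len(records))),
    }
    if plan.mode == "leave_combination_out":
        audit["no_shared_pair"] = not ({r.pair_key for r in train} & {r.pair_key for r in test})
    elif plan.mode == "leave_drug_out":
        held = {tuple(h) if isinstance(h, list) else h for h in plan.held_out}
        train_drugs = {d for r in train for d in (r.drug_a_id, r.drug_b_id)}
        audit["held_drugs_absent_from_train"] = not (held & train_drugs)
        audit["test_contains_held_drug"] = all(
            r.drug_a_id in held or r.drug_b_id in held for r in test
        )
    elif plan.mode == "leave_cell_line_out":
        audit["no_shared_cell_line"] = not (
            {r.cell_line_id for r in train} & {r.cell_line_id for r in test}
        )
    return audit


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1


def early_stop_check(history: TrainingHistory, patience: int = 30,
                     rise_limit: int = 10, tol: float = 1e-4):
    """Return (stop, reason) from the validation-loss trace so far.

    ``patience_no_improve``: no decrease of the running best by >= tol for
    `patience` consecutive epochs.  ``consecutive_increase``: the loss
    strictly rose for `rise_limit` consecutive steps.
    """
    losses = history.val_loss
    if not losses:
        raise ValueError("history is empty")
    best = losses[0]
    since_improve = 0
    for loss in losses[1:]:
        if loss <= best - tol:
            best = loss
            since_improve = 0
        else:
            since_improve += 1
    if since_improve >= patience:
        return True, "patience_no_improve"
    rises = 0
    for prev, cur in zip(losses, losses[1:]):
        rises = rises + 1 if cur > prev else 0
    if rises >= rise_limit:
        return True, "consecutive_increase"
    return False, None


@dataclass
class TrainConfig:
    """Optimisation settings.

    ``weight_decay`` adds an L2 penalty on all weights; with far more
    omics features than cell lines the linear omics maps are
    underdetermined, and the ridge term both regularises and drives the
    untrained components of the weight matrices to zero, which keeps
    gradient-based attributions concentrated on informative features.
    """

    lr: float = 1e-3
    max_epochs: int = 300
    patience: int = 30
    rise_limit: int = 10
    tol: float = 1e-4
    weight_decay: float = 1e-4
    seed: int = 0


def _loss(model, bundle, records, targets, train=False, rng=None):
    preds = model.forward_records(bundle, records, train=train, rng=rng)
    y = targets
    if model.config.task == "classification":
        eps = 1e-12
        from .nn import Tensor
        yt = Tensor(y)
        return -((yt * (preds + eps).log()) + ((1.0 - yt) * (1.0 - preds + eps).log())).mean()
    from .nn import Tensor
    return ((preds - Tensor(y)) ** 2).mean()


def _targets(model_config, records):
    if model_config.task == "classification":
        return np.array([r.label for r in records], dtype=np.float64)
    return np.array([r.loewe for r in records], dtype=np.float64)


def train_model(bundle, split: SplitPlan, model_config: ModelConfig,
                train_config: TrainConfig | None = None):
    """Fit one model on the plan's training records.

    Full-batch adaptive-moment gradient descent; the parameters from the
    best validation epoch are restored before returning.  Deterministic
    given (configs, split, data).
    """
    tc = train_config or TrainConfig()
    model = SynergyModel(replace(model_config, seed=model_config.seed))
    train_records = [bundle.records[i] for i in split.train_idx]
    val_records = [bundle.records[i] for i in split.val_idx]
    if model.config.symmetrize == "augment":
        from dataclasses import replace as _rr
        train_records = train_records + [
            _rr(r, drug_a_id=r.drug_b_id, drug_b_id=r.drug_a_id,
                smiles_a=r.smiles_b, smiles_b=r.smiles_a)
            for r in train_records
        ]
    y_train = _targets(model.config, train_records)
    y_val = _targets(model.config, val_records)
    opt = Adam(model.parameters(), lr=tc.lr)
    rng = np.random.default_rng(tc.seed)
    history = TrainingHistory()
    best_val, best_state = np.inf, None
    for epoch in range(tc.max_epochs):
        opt.zero_grad()
        loss = _loss(model, bundle, train_records, y_train, train=True, rng=rng)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"training loss diverged at epoch {epoch}")
        data_loss = float(loss.data)
        if tc.weight_decay > 0:
            penalty = None
            for p in model.parameters():
                term = (p * p).sum()
                penalty = term if penalty is None else penalty + term
            loss = loss + tc.weight_decay * penalty
        loss.backward()
        opt.step()
        val_loss = float(_loss(model, bundle, val_records, y_val).data) if val_records \
            else float(loss.data)
        history.epochs.append(epoch)
        history.train_loss.append(data_loss)
        history.val_loss.append(val_loss)
        if val_loss < best_val - tc.tol or best_state is None:
            best_val = val_loss
            best_state = {k: v.data.copy() for k, v in model._params.items()}
            history.best_epoch = epoch
        stop, reason = early_stop_check(history, tc.patience, tc.rise_limit, tc.tol)
        if stop:
            history.stop_reason = reason
            break
    else:
        history.stop_reason = "max_epochs"
    for k, t in model._params.items():
        t.data = best_state[k]
    return model, history


def permute_labels(records, seed: int = 0):
    """Return records with labels and scores permuted (null-model control)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    return [
        replace(records[i], label=records[perm[i]].label, loewe=records[perm[i]].loewe)
        for i in range(len(records))
    ]


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------


@dataclass
class MetricsReport:
    task: str
    values: dict
    n: int
    seed: int = 0
    flags: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"task": self.task, "n": self.n, "seed": self.seed,
                           "values": self.values, "flags": self.flags})


def compute_metrics(y_true, y_score_or_pred, task: str, seed: int = 0) -> MetricsReport:
    """Standard metric suite.

    Classification: AUROC, AUCPR, ACC, BACC, F1 and Cohen's kappa
    (threshold 0.5 for the thresholded metrics).  Regression: RMSE, MAE,
    Pearson and Spearman correlation, R^2.  Metrics undefined on the
    given targets (e.g. AUROC with single-class truth) are flagged and
    reported as NaN rather than raising.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_hat = np.asarray(y_score_or_pred, dtype=np.float64)
    if y_true.shape != y_hat.shape or y_true.size < 2:
        raise ValueError("y_true and predictions must share a length >= 2")
    values, flags = {}, {}
    if task == "classification":
        if np.any((y_hat < 0) | (y_hat > 1)):
            raise ValueError("classification scores must lie in [0, 1]")
        pred = (y_hat >= 0.5).astype(int)
        yt = y_true.astype(int)
        single_class = len(np.unique(yt)) < 2
        if single_class:
            values["auroc"] = values["aucpr"] = float("nan")
            flags["auroc"] = flags["aucpr"] = "undefined_single_class"
        else:
            values["auroc"] = float(skm.roc_auc_score(yt, y_hat))
            values["aucpr"] = float(skm.average_precision_score(yt, y_hat))
        values["acc"] = float(skm.accuracy_score(yt, pred))
        values["bacc"] = float(skm.balanced_accuracy_score(yt, pred))
        values["f1"] = float(skm.f1_score(yt, pred, zero_division=0))
        values["kappa"] = float(skm.cohen_kappa_score(yt, pred))
    elif task == "regression":
        values["rmse"] = float(np.sqrt(skm.mean_squared_error(y_true, y_hat)))
        values["mae"] = float(skm.mean_absolute_error(y_true, y_hat))
        if np.std(y_true) == 0 or np.std(y_hat) == 0:
            values["pcc"] = values["scc"] = float("nan")
            flags["pcc"] = flags["scc"] = "undefined_constant_input"
        else:
            values["pcc"] = float(sps.pearsonr(y_true, y_hat).statistic)
            values["scc"] = float(sps.spearmanr(y_true, y_hat).statistic)
        values["r2"] = float(skm.r2_score(y_true, y_hat))
    else:
        raise ValueError(f"unknown task {task!r}")
    return MetricsReport(task=task, values=values, n=int(y_true.size), seed=seed, flags=flags)


def evaluate_model(model, bundle, record_indices, seed: int = 0) -> MetricsReport:
    """Predict on the indexed records and score against their targets."""
    records = [bundle.records[i] for i in record_indices]
    preds = model.forward_records(bundle, records).data
    y = _targets(model.config, records)
    return compute_metrics(y, preds, model.config.task, seed=seed)


def repeat_evaluate(bundle, model_config: ModelConfig,
                    train_config: TrainConfig | None = None,
                    n_repeats: int = 15, mode: str = "random",
                    seed: int = 0, **split_kwargs) -> dict:
    """Repeat split+train+test under independent seeds; t-interval on means.

    Each repeat is a fresh split and a freshly initialised model.  Returns
    ``{"n_repeats", "per_repeat", "mean", "ci_low", "ci_high"}`` with the
    confidence interval at alpha = 0.05 (Student t, n-1 df).
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    reports = []
    for rep_seed in seeds:
        rep_seed = int(rep_seed)
        plan = make_split(bundle.records, mode=mode, seed=rep_seed, **split_kwargs)
        mc = replace(model_config, seed=rep_seed)
        tc = replace(train_config or TrainConfig(), seed=rep_seed)
        mdl, _ = train_model(bundle, plan, mc, tc)
        reports.append(evaluate_model(mdl, bundle, plan.test_idx, seed=rep_seed))
    keys = reports[0].values.keys()
    out = {"n_repeats": n_repeats, "per_repeat": [r.values for r in reports],
           "mean": {}, "ci_low": {}, "ci_high": {}}
    tq = sps.t.ppf(0.975, n_repeats - 1)
    for key in keys:
        vals = np.array([r.values[key] for r in reports])
        m = float(np.nanmean(vals))
        sd = float(np.nanstd(vals, ddof=1))
        half = tq * sd / np.sqrt(n_repeats)
        out["mean"][key] = m
        out["ci_low"][key] = m - half
        out["ci_high"][key] = m + half
    return out


def tune_hyperparameters(bundle, split: SplitPlan, search_space: dict,
                         model_config: ModelConfig,
                         train_config: TrainConfig | None = None,
                         n_trials: int = 30, seed: int = 0,
                         optimizer=None) -> dict:
    """Pick the config with the lowest validation loss.

    ``optimizer`` is a pluggable hook ``(objective, search_space,
    n_trials) -> best_params``; without one, seeded random search draws
    the same trial budget from the space.  Returns ``{"best_config",
    "best_val_loss", "trials"}`` with one entry per evaluated trial.
    """
    if not search_space:
        raise ValueError("search space must be non-empty")
    rng = np.random.default_rng(seed)
    trials = []

    def objective(params: dict) -> float:
        mc = replace(model_config, **params)
        mdl, hist = train_model(bundle, split, mc, train_config)
        val = float(np.min(hist.val_loss))
        trials.append({"params": params, "val_loss": val})
        return val

    if optimizer is not None:
        best_params = optimizer(objective, search_space, n_trials)
    else:
        seen = set()
        for _ in range(n_trials):
            params = {k: v[rng.integers(len(v))] for k, v in sorted(search_space.items())}
            key = tuple(sorted(params.items()))
            if key in seen and len(seen) < np.prod([len(v) for v in search_space.values()]):
                continue
            seen.add(key)
            objective(params)
        best_params = min(trials, key=lambda t: t["val_loss"])["params"]
    best = min(trials, key=lambda t: t["val_loss"])
    return {"best_config": replace(model_config, **best_params),
            "best_val_loss": best["val_loss"], "trials": trials,
            "n_trials_requested": n_trials}
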