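"""Fine-tuning loop and evaluation.

Training minimises softmax cross-entropy over the [CLS] class scores with
Adam and an optional linear learning-rate decay.  Evaluation reports
per-class and micro-averaged precision/recall/F1 (in percent, as the field
prints them), with the negative / "no relation" class excluded from the
micro average; results can be averaged over several seeded runs and broken
down by instance length in 50-token bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .model import ModelConfig, backward_batch, forward_batch, predict_proba_scores
from .pretreat import TokenSequence

NEGATIVE_LABEL = "negative"


@dataclass
class TrainConfig:
    """Optimisation settings.

    Defaults follow the fine-tuning recipe for the full-scale model
    (3 epochs, Adam at 2e-5 with linear decay, results averaged over
    5 runs); from-scratch training of tiny models wants a larger learning
    rate (~1e-3).  Per-dataset (max_len, batch) presets: (512, 6) for the
    document-level CDR/PPIm corpora, (150, 32) for DDI, (200, 23) for CPR.
    """

    epochs: int = 3
    batch_size: int = 6
    max_len: int = 512
    learning_rate: float = 2e-5
    optimizer: str = "adam"
    lr_schedule: str = "linear"  # "linear" | "constant"
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    n_runs: int = 5

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch size >= 1")


class AdamOptimizer:
    def __init__(self, params: Mapping[str, np.ndarray], cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        b1, b2, eps = self.cfg.beta1, self.cfg.beta2, self.cfg.adam_eps
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)


def _stack_sequences(seqs: Sequence[TokenSequence]):
    ids = np.stack([np.asarray(s.ids) for s in seqs])
    seg = np.stack([np.asarray(s.segment_ids) for s in seqs])
    mask = np.stack([np.asarray(s.mask) for s in seqs])
    return ids, seg, mask


def cross_entropy(scores: np.ndarray, y: np.ndarray):
    """Mean softmax cross-entropy and its gradient wrt the scores."""
    probs = predict_proba_scores(scores)
    b = scores.shape[0]
    loss = -np.log(np.clip(probs[np.arange(b), y], 1e-12, None)).mean()
    dscores = probs.copy()
    dscores[np.arange(b), y] -= 1.0
    return loss, dscores / b


def train_model(
    params: dict[str, np.ndarray],
    mconfig: ModelConfig,
    sequences: Sequence[TokenSequence],
    y: np.ndarray,
    tcfg: TrainConfig,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Train in place-free fashion; returns (new params, per-batch loss trace).

    Deterministic for a fixed seed: shuffling, batching and dropout all
    derive from one ``numpy`` generator seeded with ``tcfg.seed``.
    ``epochs = 0`` returns the parameters unchanged.
    """
    if len(sequences) == 0:
        raise ValueError("empty training set")
    ids, seg, mask = _stack_sequences(sequences)
    y = np.asarray(y, dtype=np.int64)
    params = {k: v.copy() for k, v in params.items()}
    rng = np.random.default_rng(tcfg.seed)
    opt = AdamOptimizer(params, tcfg)
    n = len(sequences)
    steps_per_epoch = max(1, -(-n // tcfg.batch_size))
    total_steps = max(1, tcfg.epochs * steps_per_epoch)
    losses: list[float] = []
    step = 0
    for _ in range(tcfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, tcfg.batch_size):
            sel = order[start : start + tcfg.batch_size]
            scores, cache = forward_batch(
                ids[sel], seg[sel], mask[sel], params, mconfig, rng=rng
            )
            loss, dscores = cross_entropy(scores, y[sel])
            grads = backward_batch(dscores, cache, params, mconfig)
            if tcfg.lr_schedule == "linear":
                lr = tcfg.learning_rate * (1.0 - step / total_steps)
            else:
                lr = tcfg.learning_rate
            opt.step(params, grads, lr)
            losses.append(float(loss))
            step += 1
    return params, losses


def predict_scores(
    params: Mapping[str, np.ndarray],
    mconfig: ModelConfig,
    sequences: Sequence[TokenSequence],
    batch_size: int = 32,
) -> np.ndarray:
    ids, seg, mask = _stack_sequences(sequences)
    out = []
    for start in range(0, len(sequences), batch_size):
        sl = slice(start, start + batch_size)
        scores, _ = forward_batch(ids[sl], seg[sl], mask[sl], params, mconfig)
        out.append(scores)
    return np.concatenate(out, axis=0)


# metrics --------------------------------------------------------------------


@dataclass
class ClassMetrics:
    precision: float  # percent
    recall: float
    f1: float
    support: int


@dataclass
class Metrics:
    """Per-class and micro P/R/F1 in percent.

    The micro average pools true/false positives and negatives over the
    evaluated classes only, i.e. the negative ("no relation") class is
    excluded, matching the convention of the relation-extraction shared
    tasks.  For a binary task the micro figures therefore equal the
    positive class's.
    """

    per_class: dict[str, ClassMetrics]
    micro: ClassMetrics
    negative_label: str = NEGATIVE_LABEL


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    negative_label: str = NEGATIVE_LABEL,
) -> Metrics:
    """Per-class and micro precision/recall/F1 from gold and predicted labels."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    labels = sorted(set(y_true) | set(y_pred))
    p, r, f, s = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    per_class = {
        lab: ClassMetrics(100 * p[i], 100 * r[i], 100 * f[i], int(s[i]))
        for i, lab in enumerate(labels)
    }
    evaluated = [lab for lab in labels if lab != negative_label]
    if evaluated:
        mp, mr, mf, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=evaluated, average="micro", zero_division=0
        )
        support = sum(per_class[lab].support for lab in evaluated)
        micro = ClassMetrics(100 * mp, 100 * mr, 100 * mf, support)
    else:
        micro = ClassMetrics(0.0, 0.0, 0.0, 0)
    return Metrics(per_class=per_class, micro=micro, negative_label=negative_label)


def average_runs(run_metrics: Sequence[Metrics]) -> Metrics:
    """Arithmetic mean of every metric field across runs (e.g. the 5-run average)."""
    if not run_metrics:
        raise ValueError("need at least one run")
    class_sets = {tuple(sorted(m.per_class)) for m in run_metrics}
    if len(class_sets) != 1:
        raise ValueError(f"runs disagree on the class set: {sorted(class_sets)}")

    def mean_cm(items: list[ClassMetrics]) -> ClassMetrics:
        return ClassMetrics(
            precision=float(np.mean([c.precision for c in items])),
            recall=float(np.mean([c.recall for c in items])),
            f1=float(np.mean([c.f1 for c in items])),
            support=int(round(np.mean([c.support for c in items]))),
        )

    per_class = {
        lab: mean_cm([m.per_class[lab] for m in run_metrics])
        for lab in run_metrics[0].per_class
    }
    micro = mean_cm([m.micro for m in run_metrics])
    return Metrics(per_class=per_class, micro=micro,
                   negative_label=run_metrics[0].negative_label)


# length-binned analysis -----------------------------------------------------


@dataclass
class LengthBin:
    label: str
    lo: int
    hi: int | None  # None = unbounded
    positive: int = 0
    negative: int = 0
    metrics: Metrics | None = None

    @property
    def total(self) -> int:
        return self.positive + self.negative


@dataclass
class LengthBinReport:
    bin_width: int
    bins: list[LengthBin] = field(default_factory=list)


def bin_index(length: int, bin_width: int = 50, n_bins: int = 9) -> int:
    """Bin of a whitespace-token length: [1,50] → 0, [51,100] → 1, …, >400 → 8."""
    return min((max(length, 1) - 1) // bin_width, n_bins - 1)


def length_binned_eval(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    lengths: Sequence[int],
    bin_width: int = 50,
    n_bins: int = 9,
    negative_label: str = NEGATIVE_LABEL,
) -> LengthBinReport:
    """Per-bin counts and P/R/F1 with instances grouped by whitespace-token length."""
    report = LengthBinReport(bin_width=bin_width)
    for b in range(n_bins):
        lo = b * bin_width + 1
        hi = None if b == n_bins - 1 else (b + 1) * bin_width
        label = f">{(n_bins - 1) * bin_width}" if hi is None else f"{lo}-{hi}"
        report.bins.append(LengthBin(label=label, lo=lo, hi=hi))
    assignments = [bin_index(L, bin_width, n_bins) for L in lengths]
    for b, bin_ in enumerate(report.bins):
        idx = [i for i, a in enumerate(assignments) if a == b]
        sub_true = [y_true[i] for i in idx]
        sub_pred = [y_pred[i] for i in idx]
        bin_.positive = sum(1 for t in sub_true if t != negative_label)
        bin_.negative = len(sub_true) - bin_.positive
        bin_.metrics = evaluate(sub_true, sub_pred, negative_label) if idx else None
    return report


# attention reporting --------------------------------------------------------


def attention_report(
    params: Mapping[str, np.ndarray],
    mconfig: ModelConfig,
    seq: TokenSequence,
    query_tokens: Sequence[str] = ("[CLS]",),
) -> dict:
    """Final-stack attention rows for [CLS] and/or target-entity tokens.

    For every queried token string, emits one probability row per head from
    the last transformer stack, together with the token strings, for
    downstream visualisation.
    """
    from .model import export_attention

    attn = export_attention(seq, params, mconfig, mconfig.n_stacks - 1)
    n_real = seq.length
    out = {"tokens": seq.tokens[:n_real], "queries": {}}
    for token in query_tokens:
        positions = [i for i in range(n_real) if seq.tokens[i] == token]
        if not positions:
            raise ValueError(f"token {token!r} not present in the sequence")
        out["queries"][token] = [
            {"position": pos,
             "heads": [attn[h, pos, :n_real].tolist()
                       for h in range(mconfig.n_heads)]}
            for pos in positions
        ]
    return out


def train_and_evaluate_runs(
    init: dict[str, np.ndarray],
    mconfig: ModelConfig,
    train_seqs: Sequence[TokenSequence],
    y_train: np.ndarray,
    test_seqs: Sequence[TokenSequence],
    y_test: Sequence[str],
    class_names: Sequence[str],
    tcfg: TrainConfig,
) -> tuple[Metrics, list[Metrics]]:
    """Train ``n_runs`` models with seeds base+0 … base+n-1 and average metrics."""
    runs: list[Metrics] = []
    for run in range(tcfg.n_runs):
        cfg = replace(tcfg, seed=tcfg.seed + run)
        params, _ = train_model(init, mconfig, train_seqs, y_train, cfg)
        scores = predict_scores(params, mconfig, test_seqs)
        pred = [class_names[i] for i in scores.argmax(axis=1)]
        runs.append(evaluate(y_test, pred))
    return average_runs(runs), runs
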