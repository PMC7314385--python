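"""Scikit-learn-style estimator wrapping the encoder and training loop."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .model import ModelConfig, init_params, predict_proba_scores
from .pretreat import WordPieceTokenizer, build_vocab
from .train import TrainConfig, attention_report, predict_scores, train_model


class TransformerRelationClassifier(BaseEstimator, ClassifierMixin):
    """Relation classifier: k-stack self-attention encoder + [CLS] linear head.

    Follows the scikit-learn estimator contract: ``X`` is a sequence of
    (pretreated) instance texts, ``y`` the relation labels.  The model is
    trained from scratch by default; pass ``pretrained_params`` (e.g. from
    :func:`docrex.model.load_pretrained`) to fine-tune converted weights.

    Parameters
    ----------
    n_stacks, n_heads, d_model, d_ff
        Encoder size (k, h, d, m); d_ff defaults to 4·d_model.
    max_len
        Sequence width after [CLS]/[SEP] framing, truncation and padding.
    tokenizer
        A :class:`~docrex.pretreat.WordPieceTokenizer`; if None, a
        word-level vocabulary with character fallback is built from the
        training texts.
    architecture
        "standard" (post-concat projection, FFN residual + LN) or
        "literal" (the bare equation form).
    n_epochs, batch_size, learning_rate, lr_schedule, dropout, random_state
        Optimisation settings; training is deterministic given
        ``random_state``.

    Attributes
    ----------
    classes_ : ndarray of label strings, sorted.
    params_ : dict of named weight tensors after fitting.
    config_ : the resolved :class:`~docrex.model.ModelConfig`.
    loss_trace_ : per-batch training loss.
    tokenizer_ : the tokenizer used to encode inputs.
    """

    def __init__(
        self,
        n_stacks: int = 2,
        n_heads: int = 2,
        d_model: int = 32,
        d_ff: int | None = None,
        max_len: int = 128,
        tokenizer: WordPieceTokenizer | None = None,
        architecture: str = "standard",
        n_epochs: int = 3,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        lr_schedule: str = "linear",
        dropout: float = 0.1,
        random_state: int = 0,
        pretrained_params: dict | None = None,
    ) -> None:
        self.n_stacks = n_stacks
        self.n_heads = n_heads
        self.d_model = d_model
        self.d_ff = d_ff
        self.max_len = max_len
        self.tokenizer = tokenizer
        self.architecture = architecture
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.dropout = dropout
        self.random_state = random_state
        self.pretrained_params = pretrained_params

    # ------------------------------------------------------------------

    def _encode(self, X: Sequence[str]):
        return [self.tokenizer_.encode(text, self.max_len) for text in X]

    def fit(self, X: Sequence[str], y: Sequence[str]) -> "TransformerRelationClassifier":
        X = list(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.tokenizer_ = self.tokenizer or WordPieceTokenizer(build_vocab(X))
        self.config_ = ModelConfig(
            n_stacks=self.n_stacks,
            n_heads=self.n_heads,
            d_model=self.d_model,
            d_ff=self.d_ff,
            n_max=self.max_len,
            vocab_size=self.tokenizer_.vocab_size,
            n_classes=len(self.classes_),
            dropout=self.dropout,
            architecture=self.architecture,
        )
        if self.pretrained_params is not None:
            params = {k: np.asarray(v).copy()
                      for k, v in self.pretrained_params.items()}
        else:
            params = init_params(self.config_,
                                 np.random.default_rng(self.random_state))
        tcfg = TrainConfig(
            epochs=self.n_epochs,
            batch_size=self.batch_size,
            max_len=self.max_len,
            learning_rate=self.learning_rate,
            lr_schedule=self.lr_schedule,
            seed=self.random_state,
        )
        self.params_, self.loss_trace_ = train_model(
            params, self.config_, self._encode(X), y_idx, tcfg
        )
        return self

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "params_")
        return predict_scores(self.params_, self.config_, self._encode(list(X)))

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        return predict_proba_scores(self.decision_function(X))

    def predict(self, X: Sequence[str]) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[scores.argmax(axis=1)]

    def export_attention_report(self, text: str,
                                query_tokens: Sequence[str] = ("[CLS]",)) -> dict:
        """Final-stack per-head attention rows for the queried tokens."""
        check_is_fitted(self, "params_")
        seq = self.tokenizer_.encode(text, self.max_len)
        return attention_report(self.params_, self.config_, seq, query_tokens)
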