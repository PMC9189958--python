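"""Partial-likelihood training of network ensembles.

Each training epoch iterates in shuffled order over all persons who
experienced an event; mini-batches of ``batch_cases`` cases are matched
one-to-one with controls drawn uniformly (with replacement across batches
and epochs) from the case's risk set, i.e. persons whose follow-up reaches
the case's event day. Cases whose risk set is empty are skipped with a
warning. Optimization is Adam on the sampled-risk-set partial likelihood
loss; training runs for exactly ``epochs`` epochs with no early stopping.

Ensembles repeat training from ``ensemble_size`` independent random
initializations (seeds derived from ``(config.seed, member)``) and average
the members' log relative risks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .network import Adam, Batch, ModelConfig, RiskNetwork, pad_batch, \
    pair_logistic_loss
from .records import (CenteringContext, EncodedHistory, PersonRecord,
                      Vocabulary, covariate_matrix, encode_history)

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


def sample_case_control_batches(times: np.ndarray, events: np.ndarray,
                                batch_cases: int,
                                rng: np.random.Generator
                                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """One epoch of matched case-control index batches.

    Returns a list of (case_indices, control_indices) pairs covering every
    case once, in shuffled order, chunked into batches of ``batch_cases``
    (the final batch may be smaller). A control for case i is uniform on
    ``{j != i : t_j >= t_i}``; a case may serve as a control.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) < 2:
        raise TrainingError("need at least 2 persons")
    case_idx = np.flatnonzero(events)
    if case_idx.size == 0:
        raise TrainingError("no events in stratum: nothing to train on")
    order = np.argsort(times, kind="stable")
    sorted_times = times[order]
    case_idx = rng.permutation(case_idx)
    batches = []
    for start in range(0, case_idx.size, batch_cases):
        chunk = case_idx[start:start + batch_cases]
        cases, controls = [], []
        for i in chunk:
            lo = np.searchsorted(sorted_times, times[i], side="left")
            n_risk = len(times) - lo
            if n_risk <= 1:  # only the case itself is at risk
                warnings.warn(
                    f"case index {int(i)} has an empty risk set; skipped",
                    stacklevel=2)
                continue
            while True:
                j = order[lo + rng.integers(n_risk)]
                if j != i:
                    break
            cases.append(i)
            controls.append(j)
        if cases:
            batches.append((np.array(cases), np.array(controls)))
    return batches


@dataclass
class EncodedStratum:
    """A stratum pre-encoded once for repeated batch construction."""

    histories: list[EncodedHistory]
    covariates: np.ndarray
    times: np.ndarray
    events: np.ndarray

    @classmethod
    def build(cls, stratum: list[PersonRecord], vocab: Vocabulary,
              centering: CenteringContext, predictor_set: str
              ) -> "EncodedStratum":
        return cls(
            histories=[encode_history(p, vocab) for p in stratum],
            covariates=covariate_matrix(stratum, centering, predictor_set),
            times=np.array([p.follow_up_days for p in stratum], dtype=float),
            events=np.array([p.cvd_event for p in stratum], dtype=bool),
        )

    def subset_batch(self, idx: np.ndarray, max_len: int) -> Batch:
        return pad_batch([self.histories[i] for i in idx],
                         self.covariates[idx], max_len)


@dataclass
class TrainedEnsemble:
    """Independently initialized trained members plus their data contracts.

    The ensemble prediction is the arithmetic mean of member log relative
    risks. The vocabulary and centering context the members were trained
    with travel with the ensemble and must be used for any prediction.
    """

    members: list[RiskNetwork]
    config: ModelConfig
    vocab: Vocabulary
    centering: CenteringContext
    loss_traces: list[list[float]]

    def predict_log_risk(self, persons: list[PersonRecord],
                         chunk: int = 512) -> np.ndarray:
        data = EncodedStratum(
            histories=[encode_history(p, self.vocab) for p in persons],
            covariates=covariate_matrix(persons, self.centering,
                                        self.config.predictor_set),
            times=np.zeros(len(persons)), events=np.zeros(len(persons),
                                                          dtype=bool))
        return predict_log_risk_encoded(self, data, chunk=chunk)


def predict_log_risk_encoded(ensemble: TrainedEnsemble,
                             data: EncodedStratum,
                             chunk: int = 512) -> np.ndarray:
    """Mean member log risk for pre-encoded persons (evaluation mode)."""
    n = len(data.histories)
    out = np.zeros(n)
    max_len = ensemble.config.max_sequence_length
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        batch = data.subset_batch(idx, max_len)
        for member in ensemble.members:
            f, _ = member.forward(batch, training=False)
            out[idx] += f
    return out / len(ensemble.members)


def train_member(data: EncodedStratum, config: ModelConfig,
                 vocab_size: int, seed_key: tuple
                 ) -> tuple[RiskNetwork, list[float]]:
    """Train one network member for exactly ``config.epochs`` epochs."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=seed_key)
    init_rng, batch_rng, drop_rng = [np.random.default_rng(s)
                                     for s in ss.spawn(3)]
    net = RiskNetwork(config, vocab_size=vocab_size,
                      n_covariates=data.covariates.shape[1], rng=init_rng)
    opt = Adam(net.params, lr=config.learning_rate, betas=config.adam_betas)
    trace: list[float] = []
    for epoch in range(config.epochs):
        batches = sample_case_control_batches(
            data.times, data.events, config.batch_cases, batch_rng)
        losses = []
        for case_ids, control_ids in batches:
            idx = np.concatenate([case_ids, control_ids])
            batch = data.subset_batch(idx, config.max_sequence_length)
            f, cache = net.forward(batch, training=True, drop_rng=drop_rng)
            k = len(case_ids)
            loss, d_case, d_control = pair_logistic_loss(f[:k], f[k:])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch + 1} "
                    f"(member seed {seed_key})")
            df = np.concatenate([d_case, d_control])
            grads = net.backward(cache, df)
            opt.step(grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)) if losses else float("nan"))
        logger.debug("member %s epoch %d/%d mean loss %.5f",
                     seed_key, epoch + 1, config.epochs, trace[-1])
    return net, trace


def train_ensemble(stratum: list[PersonRecord], config: ModelConfig,
                   vocab: Vocabulary,
                   centering: CenteringContext) -> TrainedEnsemble:
    """Train ``config.ensemble_size`` members on one (training) stratum.

    ``vocab`` and ``centering`` must have been fitted on this training
    stratum only; they are stored with the ensemble so predictions on new
    persons reuse the training-data contracts.
    """
    data = EncodedStratum.build(stratum, vocab, centering,
                                config.predictor_set)
    members, traces = [], []
    for k in range(config.ensemble_size):
        net, trace = train_member(data, config, len(vocab), seed_key=(k,))
        members.append(net)
        traces.append(trace)
    return TrainedEnsemble(members=members, config=config, vocab=vocab,
                           centering=centering, loss_traces=traces)
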