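"""Window-local Markov null model for expected PQS frequency.

A k-th order Markov chain (default order 2) is fitted to the observed
sequence in consecutive windows (default 150 bp).  Randomized control
sequences are generated window by window, preserving each window's length
and local short-range composition, and scanned for PQS clusters; the
resulting density over replicates is the expected-frequency baseline used
to judge whether observed PQS counts exceed what GC/trinucleotide content
alone would produce.

Contexts never span window boundaries (each window has an independent
model).  Positions whose (context, next-symbol) slice contains N contribute
nothing to the counts; generated sequence is always over {A,C,G,T}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scanner import ScanParams, scan_both

__all__ = [
    "MarkovModel",
    "NullEstimate",
    "fit_markov",
    "generate",
    "expected_pqs_density",
]

ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(ALPHABET)}

DEFAULT_ORDER = 2
DEFAULT_WINDOW = 150
DEFAULT_REPLICATES = 100
# 1/|alphabet| per transition: sparse 150 bp windows still define a proper chain
DEFAULT_PSEUDOCOUNT = 0.25


@dataclass
class MarkovModel:
    """Transition counts from each ``order``-length context to each symbol."""

    order: int
    pseudocount: float
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    n_transitions: int = 0
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def fitted(self) -> bool:
        return self.n_transitions > 0 or bool(self.counts)

    def probs(self, context: str) -> np.ndarray:
        c = self.counts.get(context)
        base = np.full(4, self.pseudocount)
        if c is not None:
            base = base + c
        total = base.sum()
        if total == 0:  # pseudocount 0 and unseen context
            return np.full(4, 0.25)
        return base / total

    def cumprobs(self, context: str) -> np.ndarray:
        """Cumulative transition probabilities for inverse-CDF sampling."""
        cp = self._cum.get(context)
        if cp is None:
            cp = self._cum[context] = np.cumsum(self.probs(context))
        return cp

    def context_distribution(self) -> tuple[list[str], np.ndarray]:
        """Observed contexts and their empirical frequencies."""
        ctxs = sorted(self.counts)
        weights = np.array([self.counts[c].sum() for c in ctxs], dtype=float)
        return ctxs, weights / weights.sum()


@dataclass
class NullEstimate:
    """Expected PQS cluster density (per kb) under the Markov null."""

    expected_pqs_per_kb: float
    ci_low: float
    ci_high: float
    n_replicates: int
    seed: int
    observed_pqs_per_kb: float | None = None


def fit_markov(
    seq: str,
    order: int = DEFAULT_ORDER,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> MarkovModel:
    """Fit a k-th order Markov chain to ``seq``.

    Every (context, next symbol) occurrence is tallied; slices containing N
    (or other non-ACGT characters) are skipped.  Raises for sequences of
    length <= order.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    seq = seq.upper()
    if len(seq) <= order:
        raise ValueError(f"sequence of length {len(seq)} too short for order {order}")
    model = MarkovModel(order=order, pseudocount=pseudocount)
    counts = model.counts
    n_ok = 0
    for i in range(len(seq) - order):
        chunk = seq[i : i + order + 1]
        if any(c not in _IDX for c in chunk):
            continue
        ctx = chunk[:order]
        arr = counts.get(ctx)
        if arr is None:
            arr = counts[ctx] = np.zeros(4)
        arr[_IDX[chunk[order]]] += 1
        n_ok += 1
    model.n_transitions = n_ok
    return model


def generate(model: MarkovModel, length: int, seed: int | np.random.Generator) -> str:
    """Sample a sequence of exactly ``length`` bases from the chain.

    The initial context is drawn from the observed context frequencies.
    Identical ``(model, length, seed)`` always yields the identical string.
    """
    if not model.fitted:
        raise ValueError("model is not fitted")
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if length == 0:
        return ""
    if model.counts:
        ctxs, w = model.context_distribution()
        ctx = ctxs[rng.choice(len(ctxs), p=w)]
    else:  # degenerate: nothing observed (e.g. all-N window) -> uniform
        ctx = "".join(
            ALPHABET[i] for i in rng.integers(0, 4, size=max(model.order, 1))
        )[: model.order]
    out = list(ctx[:length])
    if len(out) < length:
        u = rng.random(length - len(out))  # one inverse-CDF draw per base
        for x in u:
            k = min(3, int(np.searchsorted(model.cumprobs(ctx), x, side="right")))
            sym = ALPHABET[k]
            out.append(sym)
            ctx = (ctx + sym)[-model.order :] if model.order > 0 else ""
    return "".join(out)


def _windows(n: int, window_len: int, order: int) -> list[tuple[int, int]]:
    """Consecutive windows tiling [0, n); a final fragment shorter than
    order+1 is merged into the preceding window so total length is conserved."""
    if n <= 0:
        raise ValueError("empty sequence")
    edges = list(range(0, n, window_len)) + [n]
    spans = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    if len(spans) > 1 and spans[-1][1] - spans[-1][0] <= order:
        a, _ = spans[-2]
        spans[-2:] = [(a, n)]
    return spans


def expected_pqs_density(
    seq: str,
    params: ScanParams | None = None,
    window_len: int = DEFAULT_WINDOW,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    order: int = DEFAULT_ORDER,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> NullEstimate:
    """Expected PQS cluster density (both strands, per kb) under the null.

    ``seq`` is partitioned into ``window_len`` windows, one model fitted per
    window, and per replicate a same-length randomized window is generated
    for each; the concatenation is scanned with the PQS scanner on both
    strands.  Returns the mean density and 2.5/97.5 percentile bounds over
    replicates, alongside the observed density of ``seq`` itself.

    Randomness: one root seed; the stream for replicate ``r`` and window
    ``w`` is derived as ``default_rng([seed, r, w])`` so serial and
    parallel evaluation orders agree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    params = params or ScanParams()
    seq = seq.upper()
    spans = _windows(len(seq), window_len, order)
    models = [fit_markov(seq[a:b], order=order, pseudocount=pseudocount) for a, b in spans]
    kb = len(seq) / 1000.0
    densities = np.empty(n_replicates)
    for r in range(n_replicates):
        parts = []
        for w, ((a, b), model) in enumerate(zip(spans, models)):
            rng = np.random.default_rng([seed, r, w])
            parts.append(generate(model, b - a, rng))
        rand_seq = "".join(parts)
        densities[r] = len(scan_both(rand_seq, params)) / kb
    observed = len(scan_both(seq, params)) / kb
    return NullEstimate(
        expected_pqs_per_kb=float(densities.mean()),
        ci_low=float(np.percentile(densities, 2.5)),
        ci_high=float(np.percentile(densities, 97.5)),
        n_replicates=n_replicates,
        seed=seed,
        observed_pqs_per_kb=observed,
    )
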