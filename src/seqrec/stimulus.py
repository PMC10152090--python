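"""Information content and entropy of symbolic melodies.

A melody is a sequence of integer tone symbols.  A predictive n-gram model
assigns each event a conditional probability given its preceding context;
the information content of an event is IC = log2(1/p) — the minimum number
of bits needed to encode it — and the entropy of a context is the expected
IC of the next event, H = sum_e p(e | ctx) * IC(e | ctx).  H is 0 when one
event is certain and log2(|A|) when all events are equally likely.

This is a deliberately minimal stand-in for corpus-trained melodic
expectation systems (multiple-viewpoint models): a single add-k-smoothed
n-gram suffices to implement and test the IC/entropy formalism itself.
Events at the start of a melody, whose full-length context is unavailable,
are scored with the longest context the model can form (shortest-context
fallback); a context never seen in training backs off to the uniform
distribution over the alphabet.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NGramModel",
    "ToneInfoProfile",
    "fit_ngram",
    "information_content",
    "entropy",
    "match_sets",
    "profile_melody",
    "read_melodies",
    "write_melodies",
    "write_profiles_tsv",
]


class ZeroProbabilityError(ValueError):
    """An event has probability 0 under the model (infinite IC)."""


@dataclass
class NGramModel:
    """Markov model of order ``order`` (context length = order) with add-k
    smoothing over a fixed alphabet."""

    order: int
    alphabet: tuple[int, ...]
    counts: dict  # context tuple -> Counter of next symbols
    smoothing: float

    def prob(self, symbol, context) -> float:
        """p(symbol | context); uses the longest known suffix of ``context``
        not exceeding the model order, uniform if no context was ever seen."""
        if symbol not in set(self.alphabet):
            raise ValueError(f"symbol {symbol!r} not in alphabet")
        ctx = tuple(context)[-self.order:] if self.order > 0 else ()
        # shortest-context fallback for melody starts / unseen contexts
        while ctx not in self.counts and len(ctx) > 0:
            ctx = ctx[1:]
        if ctx not in self.counts:
            return 1.0 / len(self.alphabet)
        c = self.counts[ctx]
        total = sum(c.values())
        k = self.smoothing
        p = (c.get(symbol, 0) + k) / (total + k * len(self.alphabet))
        if p == 0.0:
            raise ZeroProbabilityError(
                f"p({symbol} | {ctx}) = 0 with smoothing 0: infinite IC"
            )
        return p

    def distribution(self, context) -> np.ndarray:
        return np.array([self.prob(e, context) for e in self.alphabet])


@dataclass
class ToneInfoProfile:
    """Per-event information profile of one melody."""

    ic: np.ndarray       # bits, one per event
    entropy: np.ndarray  # bits, one per event context

    def __post_init__(self):
        self.ic = np.asarray(self.ic, dtype=float)
        self.entropy = np.asarray(self.entropy, dtype=float)


def fit_ngram(corpus, order: int, smoothing: float = 1.0,
              alphabet=None) -> NGramModel:
    """MLE counts with add-k smoothing; contexts of every length up to
    ``order`` are tabulated so melody-initial events can be scored."""
    corpus = [list(seq) for seq in corpus]
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("corpus is empty")
    if order < 1:
        raise ValueError("order must be >= 1")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    if alphabet is None:
        alphabet = sorted({e for seq in corpus for e in seq})
    if len(alphabet) == 0:
        raise ValueError("empty alphabet")
    counts: dict = defaultdict(Counter)
    for seq in corpus:
        for i, e in enumerate(seq):
            for m in range(0, order + 1):
                if i - m < 0:
                    break
                counts[tuple(seq[i - m:i])][e] += 1
    return NGramModel(order=order, alphabet=tuple(alphabet),
                      counts=dict(counts), smoothing=float(smoothing))


def information_content(model: NGramModel, sequence) -> np.ndarray:
    """Per-event IC (bits): log2(1 / p(e_i | context))."""
    seq = list(sequence)
    out = np.empty(len(seq))
    for i, e in enumerate(seq):
        p = model.prob(e, seq[max(0, i - model.order):i])
        out[i] = np.log2(1.0 / p)
    return out


def entropy(model: NGramModel, context) -> float:
    """Entropy (bits) of the next-event distribution given ``context``:
    H = sum_e p(e|ctx) IC(e|ctx).  Zero iff the distribution is degenerate."""
    h = 0.0
    for e in model.alphabet:
        try:
            p = model.prob(e, context)
        except ZeroProbabilityError:
            continue  # lim p->0 of p*log2(1/p) is 0
        h += p * np.log2(1.0 / p)
    return float(h)


def profile_melody(model: NGramModel, sequence) -> ToneInfoProfile:
    seq = list(sequence)
    ic = information_content(model, seq)
    h = np.array([entropy(model, seq[max(0, i - model.order):i])
                  for i in range(len(seq))])
    return ToneInfoProfile(ic=ic, entropy=h)


def match_sets(profiles_M, profiles_N, tolerance: float = 0.5) -> dict:
    """Compare mean +/- sd IC and entropy between two stimulus sets, as done
    when equating memorized and novel melodies on information measures."""
    if not profiles_M or not profiles_N:
        raise ValueError("both stimulus sets must be nonempty")

    def _stats(profiles, attr):
        vals = np.concatenate([getattr(p, attr) for p in profiles])
        return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    report = {"tolerance": float(tolerance)}
    matched = True
    for attr, key in (("ic", "IC"), ("entropy", "H")):
        mM, sM = _stats(profiles_M, attr)
        mN, sN = _stats(profiles_N, attr)
        diff = abs(mM - mN)
        report[key] = {
            "mean_M": mM, "sd_M": sM, "mean_N": mN, "sd_N": sN,
            "abs_mean_difference": diff, "matched": bool(diff <= tolerance),
        }
        matched &= diff <= tolerance
    report["matched"] = bool(matched)
    return report


# ---------------------------------------------------------------------------
# plain-text I/O: one integer melody per line, TSV profiles
# ---------------------------------------------------------------------------

def read_melodies(path) -> list[list[int]]:
    melodies = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if line:
                melodies.append([int(x) for x in line.split()])
    return melodies


def write_melodies(path, melodies) -> None:
    with open(path, "w") as f:
        for seq in melodies:
            f.write(" ".join(str(int(x)) for x in seq) + "\n")


def write_profiles_tsv(path, profiles) -> None:
    with open(path, "w") as f:
        f.write("melody\tevent\tic_bits\tentropy_bits\n")
        for m, p in enumerate(profiles):
            for i, (ic, h) in enumerate(zip(p.ic, p.entropy)):
                f.write(f"{m}\t{i}\t{ic:.6f}\t{h:.6f}\n")
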