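"""Collapsed Gibbs sampler for latent Dirichlet allocation.

Documents are cells, words are binned locus pairs.  The sampler keeps the
usual document-topic / word-topic count tables and resamples every token's
topic assignment from its full conditional.  A numba kernel carries the hot
loop; a pure-python twin with identical semantics is used if numba is
unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _gibbs_loop(doc, word, topic, n_dt, n_wt, n_t, alpha, beta, n_iter, seed):
    np.random.seed(seed)
    n_topics = n_t.size
    vocab = n_wt.shape[0]
    probs = np.empty(n_topics)
    for _ in range(n_iter):
        for i in range(doc.size):
            d = doc[i]
            w = word[i]
            t = topic[i]
            n_dt[d, t] -= 1
            n_wt[w, t] -= 1
            n_t[t] -= 1
            cum = 0.0
            for k in range(n_topics):
                cum += ((n_dt[d, k] + alpha) * (n_wt[w, k] + beta)
                        / (n_t[k] + vocab * beta))
                probs[k] = cum
            u = np.random.random() * cum
            t_new = 0
            while t_new < n_topics - 1 and probs[t_new] < u:
                t_new += 1
            topic[i] = t_new
            n_dt[d, t_new] += 1
            n_wt[w, t_new] += 1
            n_t[t_new] += 1


def run_gibbs(doc: np.ndarray, word: np.ndarray, n_docs: int, vocab: int,
              n_topics: int, alpha: float, beta: float, n_iter: int,
              seed: int) -> np.ndarray:
    """Run collapsed Gibbs sampling; returns the document-topic count table."""
    rng = np.random.default_rng(seed)
    topic = rng.integers(0, n_topics, size=doc.size).astype(np.int64)
    n_dt = np.zeros((n_docs, n_topics), dtype=np.int64)
    n_wt = np.zeros((vocab, n_topics), dtype=np.int64)
    n_t = np.zeros(n_topics, dtype=np.int64)
    np.add.at(n_dt, (doc, topic), 1)
    np.add.at(n_wt, (word, topic), 1)
    np.add.at(n_t, topic, 1)
    if n_topics > 1 and n_iter > 0:
        _gibbs_loop(doc.astype(np.int64), word.astype(np.int64), topic,
                    n_dt, n_wt, n_t, float(alpha), float(beta), int(n_iter),
                    int(seed) % (2**31 - 1))
    return n_dt
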