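"""Numba kernels for collapsed Gibbs sampling of LDA.

The corpus is token-expanded: parallel int32 arrays of document index and
word index, one entry per token.  ``gibbs_fit`` samples token-topic
assignments with both topic-word and document-topic counts free;
``gibbs_fold_in`` freezes the topic-word distributions and resamples only the
document-topic counts, which is the transfer ("fold-in") mechanism.

Point estimates are posterior means averaged over post-burn-in sweeps
(every ``thin``-th sweep), which is noticeably more stable than the final
sample alone.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sample_discrete(p: np.ndarray, total: float) -> int:
    r = np.random.random() * total
    acc = 0.0
    for k in range(p.shape[0]):
        acc += p[k]
        if r <= acc:
            return k
    return p.shape[0] - 1


@njit(cache=True)
def gibbs_fit(
    doc_idx: np.ndarray,
    word_idx: np.ndarray,
    n_docs: int,
    n_words: int,
    n_topics: int,
    alpha: float,
    eta: float,
    n_sweeps: int,
    burn_in: int,
    thin: int,
    seed: int,
):
    """Collapsed Gibbs sampler; returns (phi, theta, log-likelihood trace)."""
    np.random.seed(seed)
    n_tokens = doc_idx.shape[0]
    z = np.empty(n_tokens, dtype=np.int32)
    ndk = np.zeros((n_docs, n_topics), dtype=np.float64)
    nkw = np.zeros((n_topics, n_words), dtype=np.float64)
    nk = np.zeros(n_topics, dtype=np.float64)
    for i in range(n_tokens):
        k = np.random.randint(n_topics)
        z[i] = k
        ndk[doc_idx[i], k] += 1.0
        nkw[k, word_idx[i]] += 1.0
        nk[k] += 1.0

    phi_sum = np.zeros((n_topics, n_words), dtype=np.float64)
    theta_sum = np.zeros((n_docs, n_topics), dtype=np.float64)
    n_samples = 0
    loglik = np.zeros(n_sweeps, dtype=np.float64)
    p = np.empty(n_topics, dtype=np.float64)
    veta = n_words * eta

    for sweep in range(n_sweeps):
        ll = 0.0
        for i in range(n_tokens):
            d = doc_idx[i]
            w = word_idx[i]
            k = z[i]
            ndk[d, k] -= 1.0
            nkw[k, w] -= 1.0
            nk[k] -= 1.0
            total = 0.0
            for t in range(n_topics):
                p[t] = (ndk[d, t] + alpha) * (nkw[t, w] + eta) / (nk[t] + veta)
                total += p[t]
            k = _sample_discrete(p, total)
            z[i] = k
            ndk[d, k] += 1.0
            nkw[k, w] += 1.0
            nk[k] += 1.0
            ll += np.log(total)
        loglik[sweep] = ll
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            n_samples += 1
            for t in range(n_topics):
                for w in range(n_words):
                    phi_sum[t, w] += (nkw[t, w] + eta) / (nk[t] + veta)
            for d in range(n_docs):
                row = 0.0
                for t in range(n_topics):
                    row += ndk[d, t] + alpha
                for t in range(n_topics):
                    theta_sum[d, t] += (ndk[d, t] + alpha) / row

    phi = phi_sum / n_samples
    theta = theta_sum / n_samples
    # enforce exact row normalization after averaging
    for t in range(n_topics):
        phi[t] /= phi[t].sum()
    for d in range(n_docs):
        theta[d] /= theta[d].sum()
    return phi, theta, loglik


@njit(cache=True)
def gibbs_fold_in(
    doc_idx: np.ndarray,
    word_idx: np.ndarray,
    n_docs: int,
    phi: np.ndarray,
    alpha: float,
    n_sweeps: int,
    burn_in: int,
    seed: int,
):
    """Infer document-topic weights with the topic-word matrix frozen."""
    np.random.seed(seed)
    n_topics = phi.shape[0]
    n_tokens = doc_idx.shape[0]
    z = np.empty(n_tokens, dtype=np.int32)
    ndk = np.zeros((n_docs, n_topics), dtype=np.float64)
    for i in range(n_tokens):
        k = np.random.randint(n_topics)
        z[i] = k
        ndk[doc_idx[i], k] += 1.0

    theta_sum = np.zeros((n_docs, n_topics), dtype=np.float64)
    n_samples = 0
    p = np.empty(n_topics, dtype=np.float64)

    for sweep in range(n_sweeps):
        for i in range(n_tokens):
            d = doc_idx[i]
            w = word_idx[i]
            k = z[i]
            ndk[d, k] -= 1.0
            total = 0.0
            for t in range(n_topics):
                p[t] = (ndk[d, t] + alpha) * phi[t, w]
                total += p[t]
            k = _sample_discrete(p, total)
            z[i] = k
            ndk[d, k] += 1.0
        if sweep >= burn_in:
            n_samples += 1
            for d in range(n_docs):
                row = 0.0
                for t in range(n_topics):
                    row += ndk[d, t] + alpha
                for t in range(n_topics):
                    theta_sum[d, t] += (ndk[d, t] + alpha) / row

    theta = theta_sum / n_samples
    for d in range(n_docs):
        theta[d] /= theta[d].sum()
    return theta
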