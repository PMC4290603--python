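import numpy as np
import pytest
import scipy.sparse as sp

from smcc.data import NetworkedDataset


def random_dataset(rng, n=5, m=4, k=3, n_labeled=2, edge_p=0.4):
    """Small random valid dataset for unit/property tests."""
    adj = np.triu((rng.random((n, n)) < edge_p).astype(float), 1)
    adj = adj + adj.T
    counts = rng.poisson(2.0, size=(n, m)).astype(float)
    labels = np.zeros((n, k), dtype=np.int8)
    mask = np.zeros(n, dtype=bool)
    labeled = rng.choice(n, size=n_labeled, replace=False)
    mask[labeled] = True
    for i in labeled:
        pos = rng.choice(k, size=rng.integers(1, k + 1), replace=False)
        labels[i, pos] = 1
    return NetworkedDataset(
        node_ids=[f"n{i}" for i in range(n)],
        adjacency=sp.csr_array(adj),
        counts=counts,
        labels=labels,
        labeled_mask=mask,
        class_names=[f"c{j + 1}" for j in range(k)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)


# ---------------------------------------------------------------------------
# independent clean-room pLSA oracle (naive loops; shares nothing with the
# package's vectorized EM path)


def plsa_oracle_fit(counts, pwc0, pcx0, n_iter, clamp_rows=None):
    """Textbook pLSA EM with explicit triple loops.

    ``clamp_rows`` maps row index -> fixed probability vector, re-applied
    after every M-step (semi-supervised variant).  Returns (pwc, pcx, L).
    """
    counts = np.asarray(counts, float)
    pwc = np.array(pwc0, float, copy=True)
    pcx = np.array(pcx0, float, copy=True)
    n, m = counts.shape
    k = pwc.shape[1]
    for _ in range(n_iter):
        num_wc = np.zeros((m, k))
        num_cx = np.zeros((n, k))
        for i in range(n):
            for j in range(m):
                if counts[i, j] == 0:
                    continue
                post = np.array([pwc[j, c] * pcx[i, c] for c in range(k)])
                tot = post.sum()
                post = post / tot if tot > 0 else np.full(k, 1.0 / k)
                for c in range(k):
                    num_wc[j, c] += counts[i, j] * post[c]
                    num_cx[i, c] += counts[i, j] * post[c]
        for c in range(k):
            col = num_wc[:, c].sum()
            if col > 0:
                pwc[:, c] = num_wc[:, c] / col
        for i in range(n):
            tot = num_cx[i].sum()
            if tot > 0:
                pcx[i] = num_cx[i] / tot
        if clamp_rows:
            for i, row in clamp_rows.items():
                pcx[i] = row
    ll = 0.0
    for i in range(n):
        for j in range(m):
            if counts[i, j] > 0:
                mix = sum(pwc[j, c] * pcx[i, c] for c in range(k))
                ll += counts[i, j] * np.log(max(mix, 1e-12))
    return pwc, pcx, ll
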