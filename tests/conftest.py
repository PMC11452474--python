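import numpy as np
import pytest

import phaseconn as pc


@pytest.fixture(scope="session")
def small_bundle():
    """A tiny planted study reused across tests (3 subjects, 6 trials,
    500 Hz for speed; planted theta F4-CP4 and alpha FC6-P6 edges)."""
    cfg = pc.StudyConfig(n_subjects=3, n_trials_per_condition=6, seed=2024,
                         fs=500.0)
    return pc.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_band_wpli(small_bundle):
    """Band-averaged WPLI tensor of the small study."""
    processed = {
        sid: {cond: pc.preprocess_epochs(ep, target_fs=500.0)
              for cond, ep in conds.items()}
        for sid, conds in small_bundle.epochs.items()
    }
    arr, subjects, ch_names = pc.collect_band_wpli(processed)
    return arr, subjects, ch_names


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def wpli_literal(coef: np.ndarray) -> np.ndarray:
    """Literal per-trial, per-pair evaluation of the WPLI definition.

    Independent reference used to validate the vectorized estimator:
    S_ij^k(f) = X_i^k(f) conj(X_j^k(f)); the index is |sum Im| / sum |Im|.
    """
    n_tr, n_ch, n_f = coef.shape
    out = np.zeros((n_ch, n_ch, n_f))
    for i in range(n_ch):
        for j in range(n_ch):
            if i == j:
                continue
            for f in range(n_f):
                num = 0.0
                den = 0.0
                for k in range(n_tr):
                    s = coef[k, i, f] * np.conj(coef[k, j, f])
                    num += s.imag
                    den += abs(s.imag)
                out[i, j, f] = abs(num) / den if den > 0 else 0.0
    return out


def rm_anova_brute(table: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Sums-of-squares RM-ANOVA by explicit loops (oracle)."""
    n, k = table.shape
    grand = table.mean()
    ss_cond = sum(n * (table[:, c].mean() - grand) ** 2 for c in range(k))
    ss_subj = sum(k * (table[s, :].mean() - grand) ** 2 for s in range(n))
    ss_tot = sum((table[s, c] - grand) ** 2 for s in range(n) for c in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    return (ss_cond / df1) / (ss_err / df2), (df1, df2)


def bh_brute(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct rule: reject H_(1..k*) where
    k* = max{k : p_(k) <= k/m * alpha}."""
    m = len(p)
    order = np.argsort(p)
    kstar = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * alpha:
            kstar = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:kstar]] = True
    return reject
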