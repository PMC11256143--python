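"""Small statistical utilities shared by the pipeline and its validation."""

from __future__ import annotations

from scipy import stats as _st

__all__ = ["clopper_pearson"]


def clopper_pearson(k: int, n: int, conf: float = 0.99) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n.

    Returns (lower, upper) bounds on the success probability.
    """
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(_st.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(_st.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
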