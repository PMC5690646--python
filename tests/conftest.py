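"""Shared fixtures: generated CSV fixtures and the brute-force MLE oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats


def grid_search_gaussian(prompts, probs,
                         mu_range=(-10.0, 15.0), sigma_range=(1e-3, 50.0),
                         n_grid=60, refinements=2):
    """Brute-force least-squares fit of (mu, sigma) on a refined dense grid.

    Independent of the package optimizer: evaluates the squared-error loss
    on an n_grid x n_grid lattice and zooms twice around the best cell.
    Returns (mu, sigma, sse).
    """
    prompts = np.asarray(prompts, dtype=float)
    probs = np.asarray(probs, dtype=float)
    lo_m, hi_m = mu_range
    lo_s, hi_s = sigma_range
    best = None
    for _ in range(refinements + 1):
        mus = np.linspace(lo_m, hi_m, n_grid)
        sigmas = np.geomspace(max(lo_s, 1e-6), hi_s, n_grid)
        pred = stats.norm.cdf(
            prompts[None, None, :], loc=mus[:, None, None],
            scale=sigmas[None, :, None],
        )
        sse = np.sum((probs[None, None, :] - pred) ** 2, axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (float(mus[i]), float(sigmas[j]), float(sse[i, j]))
        dm = (hi_m - lo_m) / (n_grid - 1)
        lo_m, hi_m = mus[i] - 2 * dm, mus[i] + 2 * dm
        lo_s = sigmas[max(j - 2, 0)]
        hi_s = sigmas[min(j + 2, n_grid - 1)]
    return best


@pytest.fixture
def grid_oracle():
    return grid_search_gaussian


@pytest.fixture
def responses_csv(tmp_path):
    """Write a small valid elicitation CSV; returns (path, DataFrame)."""

    def make(rows=None, name="responses.csv"):
        if rows is None:
            rows = []
            for pid in ("a", "b"):
                for cond in ("control", "treatment"):
                    lo, hi = 0.0, 6.0
                    rows.append({
                        "participant_id": pid, "question_id": "q1",
                        "condition": cond, "best": 3.0, "lo": lo, "hi": hi,
                        "c1": 1.0, "c2": 3.0, "c3": 5.0,
                        "p1": 0.2, "p2": 0.5, "p3": 0.8,
                    })
        df = pd.DataFrame(rows)
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path, df

    return make
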