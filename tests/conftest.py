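import datetime as dt

import numpy as np
import pytest

from viralphenology.core_io import AbundanceTable, RegularSeries, Sample


def markov_seq(rng, n, trans):
    """Plain order-2 Markov emission from 16x4 transition rows (oracle helper)."""
    cum = np.cumsum(trans, axis=1)
    out = [int(rng.integers(4)), int(rng.integers(4))]
    u = rng.random(n)
    for i in range(2, n):
        state = out[-2] * 4 + out[-1]
        out.append(int(np.searchsorted(cum[state], u[i], side="right")))
    return "".join("ACGT"[c] for c in out)


def rc_symmetric_chain(rng):
    """Random order-2 chain equal to its own reverse-complement chain.

    Built by symmetrizing the stationary 3-mer joint distribution of a random
    chain, so sequences it emits have strand-symmetric word statistics of
    every order.  Under both-strand k-mer counting this is the regime where
    Markov-centered residuals of independent sequences are uncorrelated.
    """
    T = rng.dirichlet(np.ones(4) * 2, size=16)
    P = np.zeros((16, 16))
    for ab in range(16):
        b = ab % 4
        for c in range(4):
            P[ab, b * 4 + c] = T[ab, c]
    evals, evecs = np.linalg.eig(P.T)
    pi = np.abs(np.real(evecs[:, np.argmax(np.real(evals))]))
    pi /= pi.sum()
    comp = np.array([3, 2, 1, 0])
    j = np.zeros((4, 4, 4))
    for a in range(4):
        for b in range(4):
            j[a, b] = pi[a * 4 + b] * T[a * 4 + b]
    jsym = np.zeros_like(j)
    for a in range(4):
        for b in range(4):
            for c in range(4):
                jsym[a, b, c] = 0.5 * (j[a, b, c] + j[comp[c], comp[b], comp[a]])
    Ts = np.zeros((16, 4))
    for a in range(4):
        for b in range(4):
            Ts[a * 4 + b] = jsym[a, b] / jsym[a, b].sum()
    return Ts


def make_series(values, start_year=2000, start_month=1, taxon_id="t") -> RegularSeries:
    return RegularSeries(
        taxon_id=taxon_id,
        start_year=start_year,
        start_month=start_month,
        values=np.asarray(values, dtype=float),
    )


def monthly_dates(n, start_year=2000, start_month=1):
    base = start_year * 12 + start_month - 1
    return [dt.date((base + i) // 12, (base + i) % 12 + 1, 15) for i in range(n)]


def planted_profiles(peaks, per_group, noise_sd, rng):
    """Seasonal z-profiles planted in groups by peak month, plus truth labels."""
    from viralphenology.clustering import SeasonalProfile

    months = np.arange(12)
    profiles, truth = [], []
    for gi, peak in enumerate(peaks):
        base = np.exp(2.0 * np.cos(2 * np.pi * (months - peak) / 12))
        for j in range(per_group):
            noisy = base * np.exp(noise_sd * rng.normal(size=12))
            z = (noisy - noisy.mean()) / noisy.std()
            profiles.append(SeasonalProfile(f"g{gi}_t{j}", z))
            truth.append(gi)
    return profiles, truth


@pytest.fixture
def toy_table() -> AbundanceTable:
    """3 taxa x 4 monthly samples, supplied deliberately out of date order."""
    dates = monthly_dates(4)
    samples = [
        Sample("s3", dates[2], 10_000_000, "viral"),
        Sample("s1", dates[0], 10_000_000, "viral"),
        Sample("s4", dates[3], 20_000_000, "viral"),
        Sample("s2", dates[1], 10_000_000, "viral"),
    ]
    cov = np.array(
        [
            [3.0, 1.0, 4.0, 2.0],
            [0.0, 5.0, 0.0, 5.0],
            [1.0, 1.0, 1.0, 1.0],
        ]
    )
    return AbundanceTable(taxa=["tA", "tB", "tC"], samples=samples, coverage=cov)
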