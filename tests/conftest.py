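import numpy as np
import pandas as pd
import pytest

import deerheat as dh


@pytest.fixture(scope="session")
def small_study():
    """A 40-pair, 4-cohort synthetic study shared by read-only tests."""
    design = dh.HerdDesign(n_pairs=40, n_cohorts=4, n_mothers=25)
    weather, records, manifest = dh.simulate_study(design, seed=11)
    return weather, records, manifest


@pytest.fixture()
def daily_weather():
    """One deterministic year of daily weather with indices."""
    w = dh.generate_weather(2005, 1, seed=0, noise_scale=0.0)
    return dh.add_indices(w)


def random_small_instance(rng, n_max=50):
    """A random tiny growth-model instance for likelihood oracle checks.

    Returns (records, spec, params) with random covariate structure,
    grouping factors and parameter values; at most n_max records.
    """
    n = int(rng.integers(8, n_max + 1))
    n_cohort = int(rng.integers(1, 4))
    n_mother = int(rng.integers(2, 6))
    n_calf = int(rng.integers(2, 8))
    records = pd.DataFrame(
        {
            "calf_id": rng.integers(0, n_calf, n).astype(str),
            "mother_id": rng.integers(0, n_mother, n).astype(str),
            "cohort": rng.integers(2000, 2000 + n_cohort, n),
            "sex": rng.choice(["female", "male"], n),
            "calf_age_d": rng.uniform(0, 143, n),
            "calf_wt_kg": rng.uniform(8, 60, n),
            "mother_wt_kg": rng.normal(99, 10, n),
            "thi": rng.uniform(55, 75, n),
        }
    )
    extra = ["mother_wt_kg", "sex", "thi"]
    pick = lambda: tuple(
        t for t in extra if rng.random() < 0.5
    )
    res = tuple(
        g for g in ("cohort", "mother", "calf") if rng.random() < 0.8
    ) or ("calf",)
    spec = dh.GrowthModelSpec(
        asym_terms=pick(), r0_terms=pick(), lrc_terms=pick(), random_effects=res
    )
    params = dh.GrowthParams(
        beta_asym=np.concatenate([[50.0 + rng.normal(0, 5)],
                                  rng.normal(0, 1, len(spec.block_terms("asym")) - 1)]),
        beta_r0=np.concatenate([[9.0 + rng.normal(0, 1)],
                                rng.normal(0, 0.5, len(spec.block_terms("r0")) - 1)]),
        beta_lrc=np.concatenate([[-4.1 + rng.normal(0, 0.3)],
                                 rng.normal(0, 0.005, len(spec.block_terms("lrc")) - 1)]),
        sigma_groups={g: float(rng.uniform(0.5, 8)) for g in res},
        sigma_resid=float(rng.uniform(0.5, 3)),
    )
    return records, spec, params


def dense_mvn_loglik(records, spec, params):
    """Brute-force multivariate-normal log-density of the growth model.

    Builds the full n x n marginal covariance explicitly; independent of
    the Woodbury/GLS path it checks.
    """
    from deerheat.growth import _ModelMatrices, _growth_s

    mats = _ModelMatrices(records, spec)
    lrc = mats.xl @ params.beta_lrc
    s = _growth_s(lrc, mats.t)
    mu = s * (mats.xa @ params.beta_asym) + (1 - s) * (mats.xr @ params.beta_r0)
    n = mats.n
    v = params.sigma_resid**2 * np.eye(n)
    for (g, _), z in zip(mats.groups, mats.z_list):
        sd = params.sigma_groups.get(g, 0.0)
        zs = z.toarray() * s[:, None]
        v += sd**2 * zs @ zs.T
    r = records["calf_wt_kg"].to_numpy(float) - mu
    sign, logdet = np.linalg.slogdet(v)
    assert sign > 0
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(v, r)))
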