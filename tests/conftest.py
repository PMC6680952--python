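import numpy as np
import pandas as pd
import pytest

import triplot as tp


@pytest.fixture(scope="session")
def hnd_study():
    """Default healthy-Nordic matched case-control study (seed 7)."""
    return tp.generate_healthy_nordic(seed=7)


@pytest.fixture(scope="session")
def camp_study():
    """Default cross-sectional metabolic study (seed 7)."""
    return tp.generate_camp(seed=7)


@pytest.fixture(scope="session")
def hnd_tpo(hnd_study):
    """Two-component PCA TPO on the matched-study metabolites, with a
    partial-Pearson food correlation block and four OR blocks."""
    s = hnd_study
    x = tp.preprocess(tp.FeatureTable(s.metabolites))
    model = tp.pca_fit(x, 2)
    tpo = tp.make_tpo(model)
    cov = s.baseline[["outcome", "gender", "age", "bmi", "smoking",
                      "education", "physical_activity"]].astype(float)
    block = tp.partial_corr(model.scores_frame(), s.foods, cov)
    tpo = tp.add_corr(tpo, block, "foods")
    y = s.baseline["outcome"].to_numpy()
    sid = s.baseline["set_id"].to_numpy()
    adj = s.baseline[["bmi", "smoking", "education", "physical_activity",
                      "energy_intake"]].astype(float)
    clr_spec = tp.OutcomeSpec(kind="matched_binary", y=y, set_id=sid)
    lr_spec = tp.OutcomeSpec(kind="binary", y=y)
    for name, fitter, spec_, cov_ in [
            ("OR", tp.crude_clr, clr_spec, None),
            ("OR_A", tp.crude_clr, clr_spec, adj),
            ("OR_U", tp.crude_lr, lr_spec, None),
            ("OR_AU", tp.crude_lr, lr_spec, adj)]:
        fits = [fitter(model.scores[:, k], spec_, cov_)
                for k in range(model.n_comp)]
        tpo = tp.add_risk(tpo, tp.risk_block_from_fits(fits), name)
    return tpo


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    import matplotlib.pyplot as plt
    plt.close("all")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_features(rng):
    """20 x 5 random feature table, centered and scaled."""
    x = pd.DataFrame(rng.normal(size=(20, 5)),
                     columns=[f"V{i+1}" for i in range(5)])
    return tp.preprocess(tp.FeatureTable(x))


def simulate_matched_pairs(beta, n_pairs, rng):
    """Matched-pair conditional logistic data with a continuous score.

    Within each pair the case is drawn with probability
    exp(beta*x1) / (exp(beta*x1) + exp(beta*x2)).
    """
    x = rng.normal(size=(n_pairs, 2))
    p_first = 1.0 / (1.0 + np.exp(-beta * (x[:, 0] - x[:, 1])))
    case_first = rng.random(n_pairs) < p_first
    y = np.empty(2 * n_pairs)
    s = np.empty(2 * n_pairs)
    y[0::2], y[1::2] = case_first, ~case_first
    s[0::2], s[1::2] = x[:, 0], x[:, 1]
    set_id = np.repeat(np.arange(n_pairs), 2)
    return s, y.astype(float), set_id
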