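import warnings

import pytest
from hypothesis import HealthCheck, settings

from h3graft import fixtures, grafting, pipeline, stem_library
from h3graft import loop_sampling as ls

settings.register_profile(
    "suite", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

SEED = 1


@pytest.fixture(scope="session")
def toy():
    return fixtures.make_toy_complex(fixtures.FixtureSpec(seed=SEED))


@pytest.fixture(scope="session")
def stem_c1(toy):
    return stem_library.extract_template(toy, "c1")


@pytest.fixture(scope="session")
def parent_graft(toy, stem_c1):
    return grafting.graft_stem(toy, stem_c1, toy.h3_sequence())


@pytest.fixture(scope="session")
def tip_ensemble(parent_graft):
    return ls.sample_tip(parent_graft, n_samples=60, seed=3)


@pytest.fixture(scope="session")
def templates_mid(toy):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fixtures.make_stem_library(
            fixtures.FixtureSpec(seed=SEED), lengths=(12, 13, 14), toy=toy)


@pytest.fixture(scope="session")
def staged(parent_graft, tip_ensemble):
    """One candidate taken through every ensemble stage."""
    ens = tip_ensemble
    reference = ls.replace_stage(ens, ens.conformations[:40], "initial")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        culled = ls.cull_ensemble(ens, keep_rescore=40, keep_top=12)
        filtered = ls.contact_filter(culled, reference)
        minimized = ls.replace_stage(
            filtered,
            [ls.minimize_loop(c, filtered.environment)
             for c in filtered.conformations], "minimized")
        merged = ls.retain_per_stem({"c1": minimized}, keep=6)
        refined = ls.refine_ensemble(merged, 1, 2, window=5.0, seed=11)
    return {"initial": ens, "culled": culled, "filtered": filtered,
            "minimized": merged, "final": refined,
            "reference": reference}


@pytest.fixture(scope="session")
def screen_result(toy, templates_mid):
    library = fixtures.make_h3_library(
        fixtures.FixtureSpec(seed=5, h3_length_range=(12, 14),
                             library_size=13))
    cfg = pipeline.ScreenConfig(
        n_samples=60, keep_rescore=40, keep_top=12, keep_per_stem=6,
        expansions_stage1=1, expansions_stage2=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.screen(toy, library, templates_mid, cfg, seed=SEED)
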