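"""Shared fixtures: compiled fixture models and generated PEtab bundles.

Everything is session-scoped because symbolic differentiation and compilation
dominate test runtime; compiled evaluators are pure, so sharing is safe.
"""

import numpy as np
import pytest

from odesens import (
    FixtureSpec,
    compile_model,
    generate_fixture,
    get_fixture,
    load_petab,
)


@pytest.fixture(scope="session")
def fixture_models():
    """name -> (Fixture, CompiledModel) for the whole catalogue."""
    out = {}
    for name in ("decay", "conversion", "synthesis_degradation", "lotka_volterra"):
        fx = get_fixture(name)
        out[name] = (fx, compile_model(fx.model))
    fx = get_fixture("linear_chain", n=4)
    out["linear_chain4"] = (fx, compile_model(fx.model))
    return out


@pytest.fixture(scope="session")
def petab_bundles(tmp_path_factory):
    """Generated PEtab problems keyed by flavour."""
    root = tmp_path_factory.mktemp("petab")
    bundles = {}
    specs = {
        "decay": FixtureSpec(name="decay", petab=True),
        "decay_noise": FixtureSpec(name="decay", petab=True, estimate_noise=True),
        "conversion": FixtureSpec(name="conversion", petab=True),
        "preeq": FixtureSpec(
            name="synthesis_degradation", petab=True, preequilibration=True,
            sigma=0.01, t_max=1.0,
        ),
        "lotka_volterra": FixtureSpec(
            name="lotka_volterra", petab=True, sigma=0.05, t_max=3.0
        ),
    }
    for key, spec in specs.items():
        outdir = root / key
        paths = generate_fixture(spec, seed=20_000 + len(key), outdir=outdir)
        bundles[key] = paths
    return bundles


@pytest.fixture(scope="session")
def petab_problems(petab_bundles):
    return {key: load_petab(paths["yaml"]) for key, paths in petab_bundles.items()}


def max_rel_diff(a, b, floor=1e-8):
    """Elementwise relative difference on components above ``floor``."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)
    mask = np.maximum(np.abs(a), np.abs(b)) > floor
    if not np.any(mask):
        return 0.0
    return float(np.max(np.abs(a - b)[mask] / scale[mask]))
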