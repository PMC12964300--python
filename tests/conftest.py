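"""Shared fixtures: small synthetic bundles and the 20-bundle reference set."""

from __future__ import annotations

import dataclasses

import pytest

from tillercount import (
    BundleSpec,
    HoughParams,
    denoise,
    generate_bundle,
    hough_circles,
)

#: Study conditions for the validation runs: ~250 tillers per bundle,
#: wall-centerline radii uniform on [20, 54] px (matching the default radius
#: search bounds), photometric noise sd 5, no occluders.
REFERENCE_SPEC = BundleSpec(occluder_density=0.0, noise_sd=5.0)

REFERENCE_SEEDS = tuple(range(1, 21))


def small_spec(seed: int, **overrides) -> BundleSpec:
    """A quick-to-render bundle (~40 tillers) for unit-level tests."""
    base = dict(
        n_tillers=40,
        mask_shape=(420.0, 380.0),
        seed=seed,
    )
    base.update(overrides)
    return BundleSpec(**base)


@pytest.fixture(scope="session")
def default_params() -> HoughParams:
    return HoughParams()


@pytest.fixture(scope="session")
def reference_bundles(default_params):
    """20 full-size bundles (seeds 1-20) with their detections.

    Generated once per test session; used by the detector-recovery and
    perfect-correction validation tests.
    """
    out = []
    for seed in REFERENCE_SEEDS:
        spec = dataclasses.replace(REFERENCE_SPEC, seed=seed)
        img, truth = generate_bundle(spec)
        detections = hough_circles(denoise(img), default_params)
        out.append((spec, img, truth, detections))
    return out


@pytest.fixture()
def small_bundle():
    """One deterministic small bundle with truth (no detections)."""
    spec = small_spec(seed=11)
    img, truth = generate_bundle(spec)
    return spec, img, truth
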