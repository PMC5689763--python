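import numpy as np
import pytest

from nscquant.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A small but fully featured phantom stack (fast to generate)."""
    spec = PhantomSpec(
        image_size_px=160,
        tumor_semi_axes_um=(60.0, 50.0, 300.0),
        n_sections=4,
        n_nsc_total=150,
        noise_sd=1.0,
        seed=3,
    )
    pairs, truth = generate_phantom(spec)
    return spec, pairs, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noise-free phantom for exact forward/inverse checks."""
    spec = PhantomSpec(
        image_size_px=160,
        tumor_semi_axes_um=(60.0, 50.0, 300.0),
        n_sections=4,
        n_nsc_total=120,
        noise_sd=0.0,
        seed=5,
    )
    pairs, truth = generate_phantom(spec)
    return spec, pairs, truth


def bruteforce_coverage_pct(nsc_mask, tumor_mask, radius_um, pixel_size_um=1.0):
    """Independent oracle: per-pixel nearest-NSC-pixel distance search.

    Literal enumeration over tumor pixels and NSC pixels; no distance
    transform involved.
    """
    tumor_px = np.argwhere(tumor_mask)
    n_tumor = len(tumor_px)
    if n_tumor == 0:
        raise ValueError("empty tumor")
    nsc_px = np.argwhere(nsc_mask)
    if len(nsc_px) == 0:
        return 0.0
    covered = 0
    for trow, tcol in tumor_px:
        d2 = (nsc_px[:, 0] - trow) ** 2 + (nsc_px[:, 1] - tcol) ** 2
        if np.sqrt(d2.min()) * pixel_size_um <= radius_um:
            covered += 1
    return 100.0 * covered / n_tumor
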