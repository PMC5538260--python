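"""Shared fixtures: kernel parameters, synthetic bundles, lookup table, oracles."""

import numpy as np
import pytest

from fbctract.fbc_core import rfbc
from fbctract.se3_kernel import KernelParams, build_table
from fbctract.synthetic import BundleSpec, SpuriousSpec, add_spurious, make_bundle
from fbctract.tract_model import Bundle


@pytest.fixture(scope="session")
def params():
    return KernelParams()


@pytest.fixture(scope="session")
def kernel_table(params):
    """Default-resolution lookup table shared across the session."""
    return build_table(params, half_width=6.0, spacing=0.5, orientation_count=42)


@pytest.fixture(scope="session")
def bundle_spec():
    return BundleSpec(seed=7)


@pytest.fixture(scope="session")
def standard_fixture(bundle_spec):
    """30 clean streamlines + 3 planted at 45 deg, 8 mm overshoot, seed 7."""
    clean = make_bundle(bundle_spec)
    spec = SpuriousSpec(n_spurious=3, anterior_offset=8.0, angular_deviation=45.0, seed=7)
    return add_spurious(clean, spec, bundle_spec)


@pytest.fixture(scope="session")
def standard_scores(standard_fixture, params):
    return rfbc(standard_fixture, params)


@pytest.fixture(scope="session")
def toy_lattice_bundle(kernel_table):
    """Hand-written toy bundle aligned with the kernel table's lattice.

    Straight streamlines along +z (a tessellation vertex) with points and
    mutual offsets on the 0.5 mm grid, so nearest-orientation assignment and
    spatial interpolation are both exact for every pair.
    """
    dirs = kernel_table.dirs
    assert np.any(np.all(np.abs(dirs - [0.0, 0.0, 1.0]) < 1e-9, axis=1))
    z = np.arange(5) * 0.5
    offsets = [(0.0, 0.0), (1.0, 0.0), (0.5, 1.0)]
    return Bundle([np.array([[ox, oy, zi] for zi in z]) for ox, oy in offsets])


def brute_force_fbc(bundle, params, cutoff=None):
    """Literal quadruple-loop FBC oracle using the reference (numpy) kernel.

    Sums kernel contributions over streamlines j != i and points l for each
    point k of each streamline i, with optional spherical culling, exactly as
    the definition states and independently of the optimized implementation.
    """
    from fbctract.se3_kernel import eval_kernel
    from fbctract.tract_model import lift

    lifted = [lift(s) for s in bundle]
    out = []
    for i, li in enumerate(lifted):
        vals = np.zeros(len(li))
        for k in range(len(li)):
            for j, lj in enumerate(lifted):
                if j == i:
                    continue
                for l in range(len(lj)):
                    dy = lj.points[l] - li.points[k]
                    if cutoff is not None and np.linalg.norm(dy) > cutoff:
                        continue
                    vals[k] += eval_kernel(dy, lj.tangents[l], li.tangents[k], params)
        out.append(vals)
    return out


def brute_force_rfbc(bundle, params, alpha=2.0, step=0.2, cutoff=None):
    """Brute-force AFBC/RFBC from the quadruple-loop FBC."""
    profiles = brute_force_fbc(bundle, params, cutoff)
    wp = max(1, round(alpha / step))
    afbc = []
    for v in profiles:
        if len(v) <= wp:
            afbc.append(v.mean())
        else:
            afbc.append(min(v[k:k + wp].mean() for k in range(len(v) - wp + 1)))
    afbc = np.array(afbc)
    bundle_mean = np.concatenate(profiles).mean()
    return profiles, afbc, afbc / bundle_mean
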