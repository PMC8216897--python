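import numpy as np
import pytest

from ehacube.classify import CATEGORY_CODES, run_eha
from ehacube.cube import build_cube
from ehacube.simulate import default_recovery_scenario, generate_loss_raster

RECOVERY_SEED = 1


@pytest.fixture(scope="session")
def recovery_run():
    """The standard planted-truth scenario, simulated and classified once
    per session: eight well-separated patches, one per hotspot template."""
    spec, bounds = default_recovery_scenario(seed=RECOVERY_SEED)
    raster, truth, legend = generate_loss_raster(spec)
    cube = build_cube(raster, bin_size=5000.0)
    cmap = run_eha(cube)
    return {"spec": spec, "bounds": bounds, "raster": raster, "truth": truth,
            "legend": legend, "cube": cube, "cmap": cmap}


def patch_bin_bounds(bounds, spec, bin_size=5000.0):
    """Planted patch bounds converted from pixel to bin coordinates."""
    f = int(bin_size / spec.cell_size)
    return {name: (r0 // f, c0 // f, r1 // f, c1 // f)
            for name, (r0, c0, r1, c1) in bounds.items()}


def recovery_summary(run):
    """Core label, majority fraction per template, plus the background
    false-category rate, for a recovery run."""
    spec, cmap = run["spec"], run["cmap"]
    bbounds = patch_bin_bounds(run["bounds"], spec)
    cores, majority = {}, {}
    patch_mask = np.zeros_like(cmap.category, dtype=bool)
    for name, (r0, c0, r1, c1) in bbounds.items():
        br, bc = (r0 + r1) // 2, (c0 + c1) // 2
        cores[name] = cmap.category_name(br, bc)
        block = cmap.category[r0:r1, c0:c1]
        majority[name] = float((block == CATEGORY_CODES[name]).mean())
        patch_mask[r0:r1, c0:c1] = True
    background = cmap.mask & ~patch_mask
    false_rate = float((cmap.category[background] > 0).mean())
    return cores, majority, false_rate
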