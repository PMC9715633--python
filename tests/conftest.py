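import numpy as np
import pytest

from alpinepheno import imaging, synth


@pytest.fixture(scope="session")
def rhizo_stack():
    """Six-date 512x512 stack with stripes and known shifts (shared)."""
    schedule = [2.0, 3.5, 5.0, 6.5, 8.0, 9.5]
    shifts = [(0, 0), (3, -2), (1, 4), (-2, 1), (5, 0), (0, -3)]
    stack, truth = synth.gen_rhizotron_stack(
        6, (512, 512), root_schedule=schedule, stripe_amp=10.0, shifts=shifts, seed=11
    )
    return stack, truth, shifts


@pytest.fixture(scope="session")
def clean_soil():
    """A stripe-free, root-free soil texture image."""
    stack, _ = synth.gen_rhizotron_stack(
        1, (512, 512), root_schedule=[0.0], stripe_amp=0.0, seed=5, sensor_noise_sd=0.0
    )
    return stack.images[0]


@pytest.fixture(scope="session")
def aligned_cropped(rhizo_stack):
    """Destriped, aligned and cropped images with matching truth masks."""
    stack, truth, _ = rhizo_stack
    des = [imaging.destripe(im) for im in stack.images]
    al = imaging.align_stack(imaging.RhizotronStack(images=des, doys=stack.doys))
    win = imaging.common_window(al.shifts, al.images[0].shape)
    imgs = [im[win] for im in al.images]
    masks = [m[win] for m in stack.masks]
    return imgs, masks, al.shifts


def f1_score(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = (pred & truth).sum()
    fp = (pred & ~truth).sum()
    fn = (~pred & truth).sum()
    return 2.0 * tp / (2.0 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
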