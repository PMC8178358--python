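import numpy as np
import pytest

from feverscreen.types import PairedRecord


def affine_rescale(x, target_mean: float, target_sd: float) -> np.ndarray:
    """Rescale a sample so its sample mean and SD (ddof=1) are exact."""
    x = np.asarray(x, dtype=float)
    z = (x - x.mean()) / x.std(ddof=1)
    return target_mean + target_sd * z


def records_from_diffs(diffs, distance: str = "1ft", t_ref: float = 98.4):
    """Paired records whose test-minus-reference differences equal ``diffs``."""
    return [
        PairedRecord(
            subject_id=f"S{i:03d}",
            t_ref=t_ref,
            t_ncit={distance: t_ref + float(d)},
        )
        for i, d in enumerate(diffs)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def study_diffs_like_published(rng):
    """n=51 differences with sample mean −6.15 and SD 2.84/1.96 exactly."""
    raw = rng.standard_normal(51)
    return affine_rescale(raw, -6.15, 2.84 / 1.96)
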