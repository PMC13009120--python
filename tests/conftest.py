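import numpy as np
import pytest

from snapia.phantom import PhantomSpec, generate_phantom
from snapia.volume_io import BinaryMask, SubjectInputs, VoxelGrid


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(VoxelGrid(np.asarray(data, dtype=bool), spacing))


def subject_from_truth(truth, rater_masks=None, **kwargs):
    """Bundle a phantom truth into SubjectInputs (truth IA mask by default)."""
    masks = rater_masks or {"r1": truth.ia_mask}
    return SubjectInputs(
        subject_id=f"phantom-{truth.true_variant}",
        ia_masks_by_rater=masks,
        thal_left=truth.thal_left,
        thal_right=truth.thal_right,
        fraction_maps=truth.fraction_maps,
        **kwargs,
    )


@pytest.fixture(scope="session")
def phantoms():
    """One default phantom per variant, masks only (fast)."""
    return {
        v: generate_phantom(PhantomSpec(variant=v), include_fraction_maps=False)
        for v in ("simple", "broad", "double", "filiform", "bilobar", "absent", "kissing")
    }


@pytest.fixture(scope="session")
def simple_phantom_full():
    """Simple phantom at HCP-like 0.7 mm isotropic, with tissue-fraction maps.

    At 0.7 mm the IA cross-section spans ~20 voxels per slice, the regime the
    per-slice Dice gate of the protocol is meant for; 1 mm masks of a small
    simple IA are only ~9 voxels and a single boundary flip already costs
    0.2 Dice.
    """
    return generate_phantom(PhantomSpec(variant="simple", spacing=(0.7, 0.7, 0.7)))
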