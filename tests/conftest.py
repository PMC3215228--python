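import warnings

import numpy as np
import pytest

from menmorph.morphometry import (extract_slice_contours, restrict_slice_range)
from menmorph.phantom import preset_params, restricted_ground_truth, voxelize_phantom
from menmorph.reference import ACQUISITION_SPACING
from menmorph.segio import VoxelSegmentation


def make_seg(labels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), **kw):
    return VoxelSegmentation(np.asarray(labels, dtype=np.int16), spacing, origin, **kw)


def slab_seg(nx=10, ny=3, nz=4, label=3, spacing=(1.0, 1.0, 1.0)):
    """Rectangular slab of `label` surrounded by one voxel of background."""
    lab = np.zeros((nx + 2, ny, nz + 2), dtype=np.int16)
    lab[1:nx + 1, :, 1:nz + 1] = label
    return make_seg(lab, spacing)


@pytest.fixture(scope="session")
def fmed_params():
    return preset_params("F", "medial")


@pytest.fixture(scope="session")
def fmed_seg_acq(fmed_params):
    """Female-medial phantom voxelized at the acquisition spacing, noise-free."""
    return voxelize_phantom(fmed_params, spacing=ACQUISITION_SPACING)


@pytest.fixture(scope="session")
def fmed_record_acq(fmed_seg_acq):
    from menmorph.morphometry import compute_morphometry

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_morphometry(fmed_seg_acq, "medial")


def oracle_for(seg, params, compartment, bounds="centers"):
    """Restricted ground truth matched to the pipeline's actual slice set."""
    from menmorph.segio import CARTILAGE_LABEL, MENISCUS_LABEL

    cart = extract_slice_contours(seg, CARTILAGE_LABEL[compartment])
    men = extract_slice_contours(seg, [MENISCUS_LABEL[compartment]])
    ss = restrict_slice_range(cart, men)
    ys = [seg.y_mm(i) for i in ss]
    half = seg.spacing[1] / 2.0 if bounds == "slabs" else 0.0
    return restricted_ground_truth(params, min(ys) - half, max(ys) + half)
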