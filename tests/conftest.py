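import numpy as np
import pytest

from stseg import network as N
from stseg import synthetic as syn
from stseg.records import DatasetState, SegmentationRecord


@pytest.fixture(scope="session")
def small_volume():
    """One 7-slice 32x32 volume with 3 texture classes, 1 labeled slice."""
    return syn.generate_volume(syn.default_specs(3), n_slices=7, shape=(32, 32),
                               n_labeled=1, neighbour_window=3, seed=11)


@pytest.fixture(scope="session")
def tiny_volume():
    """Minimal 16x16 volume for fast training tests."""
    return syn.generate_volume(syn.default_specs(3), n_slices=7, shape=(16, 16),
                               n_labeled=1, neighbour_window=3, seed=3)


@pytest.fixture(scope="session")
def tiny_net_config():
    return N.NetworkConfig(n_classes=3, base_width=8, variant="tiny")


@pytest.fixture(scope="session")
def mini_dataset():
    """A 4-volume 16x16 split: 2 train volumes (2 labeled + 12 unlabeled
    slices), 1 val, 1 test."""
    _, state = syn.default_benchmark(seed=7, n_volumes=4, n_slices=7,
                                     shape=(16, 16), n_labeled=1,
                                     neighbour_window=3, n_classes=4)
    return state


def make_pool_dataset(volume, n_labeled: int, n_unlabeled: int) -> DatasetState:
    """A dataset of arbitrary pool sizes built by recycling a volume's slices
    under fresh image ids (for selection/quota arithmetic tests)."""
    def rec(i, labeled):
        s = i % volume.n_slices
        return SegmentationRecord(
            image_id=f"im{i:03d}", image=volume.slices[s],
            label=volume.dense_labels[s] if labeled else None,
            roi=volume.roi_masks[s],
            provenance="human" if labeled else "none")
    return DatasetState(
        labeled=[rec(i, True) for i in range(n_labeled)],
        unlabeled=[rec(100 + i, False) for i in range(n_unlabeled)],
        val=[rec(900, True)], test=[rec(950, True)])
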