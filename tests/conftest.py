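import numpy as np
import pandas as pd
import pytest

from memspt import GroundTruth, ImagingConfig, ParticlePopulation


@pytest.fixture
def small_imaging() -> ImagingConfig:
    """A small, fast observation model for unit tests."""
    return ImagingConfig(frame_rate=83.3, n_frames=200, pixel_size=0.2,
                         image_shape=(128, 128), localization_sigma=0.0,
                         camera_noise_sigma=0.0)


def make_truth(positions: pd.DataFrame, imaging: ImagingConfig,
               populations: list[ParticlePopulation], seed: int = 0
               ) -> GroundTruth:
    """Wrap a hand-written track table as a GroundTruth for rendering."""
    drift = pd.DataFrame({"frame": np.arange(imaging.n_frames),
                          "dx_um": 0.0, "dy_um": 0.0})
    return GroundTruth(true_tracks=positions, noisy_tracks=positions,
                       drift_path=drift, seed=seed, imaging=imaging,
                       populations=populations)


def point_track(x: float, y: float, n_frames: int, particle: int = 0,
                population: str = "sphere") -> pd.DataFrame:
    return pd.DataFrame({"frame": np.arange(n_frames), "particle": particle,
                         "x_um": x, "y_um": y, "population": population})
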