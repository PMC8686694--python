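import numpy as np
import pytest

from agtitrate.peaklist import Peak, PeakList, TitrationPoint, TitrationSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_peak(res: int, h: float, n: float, res_type: str = "A",
              intensity: float | None = 1e6) -> Peak:
    return Peak(f"{res_type}{res}N-H", res, res_type, shift_h=h, shift_n=n,
                intensity=intensity)


@pytest.fixture
def small_series() -> TitrationSeries:
    """Three-point series of four peaks; residue 12 drifts, 14 disappears."""
    def point(ratio, peaks):
        return TitrationPoint(
            ligand_total=ratio * 1e-3, receptor_totals={"P": 1e-3},
            molar_ratio=ratio, peaks=PeakList(peaks),
        )

    free = [make_peak(11, 8.10, 118.0), make_peak(12, 8.30, 121.0),
            make_peak(13, 7.90, 109.5), make_peak(14, 8.55, 125.0)]
    p1 = [make_peak(11, 8.10, 118.0), make_peak(12, 8.31, 121.1),
          make_peak(13, 7.90, 109.5), make_peak(14, 8.55, 125.0, intensity=2e5)]
    p2 = [make_peak(11, 8.10, 118.0), make_peak(12, 8.33, 121.2),
          make_peak(13, 7.90, 109.5)]
    return TitrationSeries(["P"], [point(0.0, free), point(1.0, p1), point(2.0, p2)])
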