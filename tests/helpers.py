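import numpy as np


def smooth_field(grid, seed, lo=0.0, hi=1.0, corr=2.0):
    """Random smooth positive field in [lo, hi]: Gaussian-filtered white noise."""
    from scipy import fft as sfft

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    k = grid.kmag()
    filt = np.exp(-0.5 * (corr * k) ** 2)
    if grid.is_1d:
        f = sfft.irfft(sfft.rfft(noise) * filt, n=grid.nx)
    else:
        f = sfft.irfft2(sfft.rfft2(noise) * filt, s=grid.shape)
    f = (f - f.min()) / (f.max() - f.min())
    return lo + (hi - lo) * f
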