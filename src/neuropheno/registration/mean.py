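"""Population-mean template construction by iterated register-and-average."""
from __future__ import annotations

import numpy as np

from ..types import ConfigurationError
from .linear import LinearTransform, register_linear, _n_angles


def build_population_mean(
    images, dof: int = 6, n_iter: int = 3, n_levels: int = 3
) -> np.ndarray:
    """Iteratively register every image to the current average and
    re-average; the template is re-centred each iteration by pulling it
    through the inverse of the mean transform, so it cannot drift toward
    any one subject. Order-invariant up to interpolation tolerance.
    """
    images = [np.asarray(im, float) for im in images]
    if len(images) < 2:
        raise ConfigurationError("population mean needs at least 2 images")
    if len({im.shape for im in images}) != 1:
        raise ConfigurationError("images must share a grid")
    template = np.mean(images, axis=0)
    ndim = template.ndim
    na = _n_angles(ndim)
    for _ in range(n_iter):
        transforms = [register_linear(im, template, dof=dof, n_levels=n_levels)
                      for im in images]
        resampled = [t.resample(im, order=3) for t, im in zip(transforms, images)]
        template = np.mean(resampled, axis=0)
        mean_t = LinearTransform(
            ndim,
            np.mean([t.angles for t in transforms], axis=0),
            np.mean([t.translation for t in transforms], axis=0),
            np.exp(np.mean([np.log(t.scales) for t in transforms], axis=0)),
            dof, transforms[0].center)
        # re-centre: carry the template toward the population centre by
        # undoing the mean template-to-subject transform
        template = mean_t.inverse().resample(template, order=3)
    return template
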