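"""Multi-echo spin-echo rendering of a labelled phantom.

Each voxel follows the mono-exponential decay S(TE) = S0 * exp(-TE/T2) of
its region's tissue parameters, with additive Gaussian or Rician noise.
The default acquisition mirrors a MEMS protocol with TE = 10 ms and an
8-echo train (echoes at 10..80 ms).
"""
from __future__ import annotations

import numpy as np

from ..types import ConfigurationError, LabelVolume, MultiEchoImage
from .config import TissueSignalModel


def default_echo_times(first_te_ms: float = 10.0, n_echoes: int = 8) -> np.ndarray:
    """Echo train TE * (1..n): 10, 20, ..., 80 ms by default."""
    return first_te_ms * np.arange(1, n_echoes + 1, dtype=float)


def render_multiecho(
    labels: LabelVolume,
    model: TissueSignalModel,
    echo_times=None,
    seed: int | None = 0,
) -> MultiEchoImage:
    """Render the noisy multi-echo stack for a label volume.

    Every label present in the volume must have an entry in the signal
    model (background label 0 maps to the ``background`` entry); an unknown
    label raises ``ConfigurationError``. Identical seeds give identical
    noise fields.
    """
    te = np.asarray(
        default_echo_times() if echo_times is None else echo_times, dtype=float)
    if te.ndim != 1 or te.size < 1 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
        raise ConfigurationError("echo times must be positive and strictly increasing")

    name_of = {0: "background"}
    name_of.update({lab: name for name, lab in labels.labels.items()})
    present = np.unique(labels.data)
    max_lab = int(present.max(initial=0))
    s0_lut = np.zeros(max_lab + 1)
    r2_lut = np.zeros(max_lab + 1)
    for lab in present:
        name = name_of.get(int(lab))
        if name is None or name not in model.s0 or name not in model.t2_ms:
            raise ConfigurationError(f"label {lab} has no tissue-model entry")
        s0_lut[lab] = model.s0[name]
        r2_lut[lab] = 1.0 / model.t2_ms[name]

    s0 = s0_lut[labels.data]
    r2 = r2_lut[labels.data]
    clean = s0[None] * np.exp(-te[:, None, None, None] * r2[None])

    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        if model.noise_model == "rician":
            n1 = rng.normal(0.0, model.noise_sd, clean.shape)
            n2 = rng.normal(0.0, model.noise_sd, clean.shape)
            data = np.sqrt((clean + n1) ** 2 + n2**2)
        else:
            data = clean + rng.normal(0.0, model.noise_sd, clean.shape)
    else:
        data = clean
    return MultiEchoImage(data=data, echo_times=te, spacing=labels.spacing)
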