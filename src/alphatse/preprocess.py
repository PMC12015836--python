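"""Re-referencing, HEOG trial rejection and regression-based blink correction.

Each step is an sklearn-style transformer (``fit``/``transform``,
``get_params``/``set_params``, fitted attributes with a trailing underscore)
operating on :class:`~alphatse.containers.EpochSet` (re-referencing also
accepts a continuous recording), so the steps chain in an
``sklearn.pipeline.Pipeline``. Module-level functions are thin wrappers.

Blink correction is a pooled per-channel least-squares regression of each
scalp channel on VEOG (over all trials and samples); the corrected signal is
``scalp − b·VEOG``. The estimated factors are returned for audit against the
generator's known propagation factors.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ContinuousRecording, EpochSet

__all__ = [
    "CommonAverageReference",
    "HeogRejector",
    "BlinkCorrector",
    "common_average_reference",
    "reject_heog",
    "correct_blinks",
]

logger = logging.getLogger(__name__)

_EOG_DEFAULT = ("VEOG", "HEOG")


class CommonAverageReference(BaseEstimator, TransformerMixin):
    """Subtract the instantaneous mean over included (non-EOG) channels.

    After the transform the mean over included channels is zero at every
    sample; excluded channels pass through untouched. Idempotent.
    """

    def __init__(self, exclude_labels: tuple[str, ...] = _EOG_DEFAULT):
        self.exclude_labels = exclude_labels

    def fit(self, x: EpochSet | ContinuousRecording, y=None):
        include = [c for c in x.channel_labels if c not in self.exclude_labels]
        if len(include) < 2:
            raise ValueError("common average reference needs ≥2 included channels")
        self.included_labels_ = include
        return self

    def transform(self, x: EpochSet | ContinuousRecording):
        if not hasattr(self, "included_labels_"):
            self.fit(x)
        out = x.copy()
        mask = np.array([c not in self.exclude_labels for c in x.channel_labels])
        if isinstance(x, EpochSet):
            out.data[:, mask, :] -= out.data[:, mask, :].mean(axis=1, keepdims=True)
        else:
            out.data[mask, :] -= out.data[mask, :].mean(axis=0, keepdims=True)
        return out


class HeogRejector(BaseEstimator, TransformerMixin):
    """Flag trials whose HEOG excursion exceeds ±``threshold_uv``.

    Strictly "exceeding": a trial peaking exactly at the threshold is kept.
    Rejection is mask-based; the data are untouched and the count is logged.
    """

    def __init__(self, threshold_uv: float = 50.0, heog_channel: str = "HEOG"):
        self.threshold_uv = threshold_uv
        self.heog_channel = heog_channel

    def fit(self, e: EpochSet, y=None):
        ih = e.channel_index(self.heog_channel)
        peak = np.max(np.abs(e.data[:, ih, :]), axis=-1)
        self.rejected_ = peak > self.threshold_uv
        self.n_rejected_ = int(self.rejected_.sum())
        return self

    def transform(self, e: EpochSet) -> EpochSet:
        self.fit(e)
        out = e.copy()
        out.reject_mask = out.reject_mask | self.rejected_
        logger.info("reject_heog: %d/%d trial(s) exceed ±%g µV (%s %s)",
                    self.n_rejected_, e.n_trials, self.threshold_uv,
                    e.subject_id, e.condition)
        return out


class BlinkCorrector(BaseEstimator, TransformerMixin):
    """Regression-based ocular correction against the VEOG channel.

    ``fit`` estimates one propagation factor per channel by least squares of
    the channel on VEOG, pooled over all non-rejected trials and samples;
    ``transform`` subtracts ``b·VEOG`` from every scalp channel. When VEOG
    variance is ~0 the correction is skipped with ``skipped_`` set.

    The regression is run on average-subtracted data (each trial minus the
    across-trial mean waveform): stimulus-locked activity such as the P3
    overlaps blink pulses with a consistent sign and would otherwise bias
    the factors, while the propagation relation is untouched by the
    subtraction.
    """

    #: pooled VEOG variance below this (µV²) means nothing to regress on
    _VAR_EPS = 1e-12

    def __init__(self, veog_channel: str = "VEOG",
                 exclude_labels: tuple[str, ...] = _EOG_DEFAULT):
        self.veog_channel = veog_channel
        self.exclude_labels = exclude_labels

    def fit(self, e: EpochSet, y=None):
        if e.n_trials < 2:
            raise ValueError("blink correction needs ≥2 trials")
        iv = e.channel_index(self.veog_channel)
        good = ~e.reject_mask
        if not good.any():
            raise ValueError("no usable trials for blink correction")
        veog = e.data[good][:, iv, :]
        v = (veog - veog.mean(axis=0, keepdims=True)).ravel()
        denom = float(v @ v)
        n_ch = e.n_channels
        self.propagation_ = np.zeros(n_ch)
        self.skipped_ = denom / v.size < self._VAR_EPS
        if self.skipped_:
            logger.warning("correct_blinks: VEOG variance ≈ 0, correction skipped")
            return self
        scalp_mask = np.array([c not in self.exclude_labels
                               for c in e.channel_labels])
        x = e.data[good][:, scalp_mask, :]
        x = x - x.mean(axis=0, keepdims=True)
        x = x.transpose(1, 0, 2).reshape(int(scalp_mask.sum()), -1)
        self.propagation_[scalp_mask] = x @ v / denom
        return self

    def transform(self, e: EpochSet) -> EpochSet:
        if not hasattr(self, "propagation_"):
            self.fit(e)
        out = e.copy()
        if self.skipped_:
            return out
        iv = e.channel_index(self.veog_channel)
        veog = e.data[:, iv, :]
        out.data -= self.propagation_[None, :, None] * veog[:, None, :]
        return out


def common_average_reference(x, exclude_labels=_EOG_DEFAULT):
    return CommonAverageReference(exclude_labels).fit(x).transform(x)


def reject_heog(e: EpochSet, heog_channel: str = "HEOG",
                threshold_uv: float = 50.0) -> EpochSet:
    return HeogRejector(threshold_uv, heog_channel).transform(e)


def correct_blinks(e: EpochSet, veog_channel: str = "VEOG"):
    """Returns ``(corrected EpochSet, per-channel propagation factors)``."""
    bc = BlinkCorrector(veog_channel).fit(e)
    return bc.transform(e), bc.propagation_
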