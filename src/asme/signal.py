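"""Preprocessing: causal band-pass, epoching, resampling, interval-mean features,
and EOG component selection/removal.

Conventions (fixed across the package):

* filtering is a single forward pass of an order-2 Butterworth band-pass
  (causal; no zero-phase filtfilt),
* epoch windows are half-open ``[tmin, tmax)`` with the onset sample at t=0,
  so the sample count is exactly ``round((tmax - tmin) * fs)``,
* events whose window runs past the end of a run draw zeros (runs are
  implicitly zero-padded),
* no baseline correction anywhere; features use the ``[0, tmax)`` part of the
  window only, the pre-stimulus prefix is kept for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal

from .synth import Recording


@dataclass(frozen=True)
class FilterSpec:
    """Order-2 causal Butterworth band-pass."""

    hp_hz: float = 1.0
    lp_hz: float = 40.0
    order: int = 2
    causal: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.hp_hz < self.lp_hz:
            raise ValueError(f"need 0 < hp < lp, got {self.hp_hz}, {self.lp_hz}")
        if self.lp_hz >= fs / 2:
            raise ValueError(f"low-pass cutoff {self.lp_hz} >= Nyquist {fs / 2}")


@dataclass
class Epochs:
    """Per-stimulus EEG windows: ``data`` is events x channels x samples."""

    data: np.ndarray
    tmin_s: float
    tmax_s: float
    fs_hz: float
    channel_labels: list[str]
    metadata: pd.DataFrame  # one row per event (run, trial, sequence, class_id, is_target, ...)

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin_s + np.arange(n) / self.fs_hz

    @property
    def labels(self) -> np.ndarray:
        """Binary target / non-target labels."""
        return self.metadata["is_target"].to_numpy().astype(int)


@dataclass
class FeatureMatrix:
    values: np.ndarray  # events x features
    feature_names: list[str]
    metadata: pd.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return self.metadata["is_target"].to_numpy().astype(int)


def bandpass(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Causal band-pass, channel-wise, single forward pass."""
    spec.validate(recording.fs_hz)
    sos = scipy.signal.butter(
        spec.order, [spec.hp_hz, spec.lp_hz], btype="bandpass", fs=recording.fs_hz,
        output="sos",
    )
    filtered = scipy.signal.sosfilt(sos, recording.data, axis=1)
    return Recording(filtered, recording.fs_hz, list(recording.channel_labels), recording.events)


def extract_epochs(
    recording: Recording,
    events: pd.DataFrame | None = None,
    tmin_s: float = -0.1,
    tmax_s: float = 1.0,
) -> Epochs:
    """Cut half-open ``[tmin, tmax)`` windows around each event onset.

    Windows reaching past the end of the recording are filled with zeros
    (the run is treated as zero-padded); epoch order preserves event order.
    """
    if tmin_s >= tmax_s:
        raise ValueError(f"tmin {tmin_s} must be < tmax {tmax_s}")
    events = recording.events if events is None else events
    fs = recording.fs_hz
    n_samp = int(round((tmax_s - tmin_s) * fs))
    n_ch, n_total = recording.data.shape
    n_ev = len(events)
    data = np.zeros((n_ev, n_ch, n_samp))
    if n_ev:
        onsets = np.round(events["onset_s"].to_numpy() * fs).astype(int)
        offset = int(round(tmin_s * fs))
        starts = onsets + offset
        idx = starts[:, None] + np.arange(n_samp)[None, :]  # events x samples
        if starts.min() >= 0 and (starts.max() + n_samp) <= n_total:
            data = np.ascontiguousarray(np.moveaxis(recording.data[:, idx], 0, 1))
        else:
            valid = (idx >= 0) & (idx < n_total)
            gathered = recording.data[:, np.clip(idx, 0, n_total - 1)]  # ch x ev x samp
            gathered = np.where(valid[None, :, :], gathered, 0.0)
            data = np.ascontiguousarray(np.moveaxis(gathered, 0, 1))
    return Epochs(
        data=data,
        tmin_s=tmin_s,
        tmax_s=tmax_s,
        fs_hz=fs,
        channel_labels=list(recording.channel_labels),
        metadata=events.reset_index(drop=True).copy(),
    )


def resample(epochs: Epochs, target_fs: float = 128.0) -> Epochs:
    """Anti-aliased polyphase resampling to ``target_fs``.

    The new sample count is ``round(duration * target_fs)``; metadata is
    unchanged.  ``target_fs == fs`` is the identity.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > epochs.fs_hz:
        raise ValueError("only downsampling is supported")
    if target_fs == epochs.fs_hz:
        return epochs
    frac = Fraction(target_fs / epochs.fs_hz).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = scipy.signal.resample_poly(epochs.data, up, down, axis=2)
    n_target = int(round((epochs.tmax_s - epochs.tmin_s) * target_fs))
    if out.shape[2] > n_target:
        out = out[:, :, :n_target]
    elif out.shape[2] < n_target:
        pad = n_target - out.shape[2]
        out = np.pad(out, ((0, 0), (0, 0), (0, pad)))
    return replace(epochs, data=out, fs_hz=float(target_fs))


def interval_means(
    epochs: Epochs,
    start_s: float = 0.0,
    end_s: float | None = None,
    bin_s: float = 0.1,
) -> FeatureMatrix:
    """Mean amplitude in consecutive non-overlapping bins, channel-major.

    With 64 channels and ten 0.1-s bins over [0, 1.0) this yields the
    640-dimensional feature vector used for classification.
    """
    end_s = epochs.tmax_s if end_s is None else end_s
    if start_s < epochs.tmin_s - 1e-9 or end_s > epochs.tmax_s + 1e-9:
        raise ValueError("feature window must lie inside the epoch window")
    n_bins_f = (end_s - start_s) / bin_s
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-6 or n_bins < 1:
        raise ValueError(f"({end_s} - {start_s}) / {bin_s} is not a positive integer")
    # bin by sample time (bins need not hold an integer number of samples,
    # e.g. 0.1 s at 128 Hz); sample i belongs to bin floor((t_i - start)/bin)
    t = epochs.times
    k = np.floor((t - start_s) / bin_s + 1e-9).astype(int)
    valid = (k >= 0) & (k < n_bins)
    counts = np.bincount(k[valid], minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError("a feature bin contains no samples at this sampling rate")
    binmat = np.zeros((t.size, n_bins))
    binmat[valid, k[valid]] = 1.0 / counts[k[valid]]
    n_ev, n_ch, _ = epochs.data.shape
    feats = epochs.data @ binmat  # events x channels x bins
    values = feats.reshape(n_ev, n_ch * n_bins)
    names = [
        f"{ch}:{start_s + k * bin_s:.1f}-{start_s + (k + 1) * bin_s:.1f}s"
        for ch in epochs.channel_labels
        for k in range(n_bins)
    ]
    return FeatureMatrix(values=values, feature_names=names, metadata=epochs.metadata)


def fit_pca_ica(data: np.ndarray, n_components: int = 15, seed: int = 0):
    """PCA to ``n_components`` followed by FastICA; returns (unmixing, mixing).

    ``sources = unmixing @ data``; ``reconstruction = mixing @ sources``.
    This is the environment-provided decomposition used for EOG cleaning;
    only the selection/removal rules below are this package's contract.
    """
    from sklearn.decomposition import PCA, FastICA

    x = data.T  # samples x channels
    mean = x.mean(axis=0)
    pca = PCA(n_components=n_components, random_state=seed)
    xp = pca.fit_transform(x - mean)
    ica = FastICA(n_components=n_components, random_state=seed, whiten="unit-variance",
                  max_iter=1000)
    ica.fit(xp)
    unmix = ica.components_ @ pca.components_  # comps x channels
    mix = np.linalg.pinv(unmix)  # channels x comps
    return unmix, mix


def pick_eog_components(
    source_timecourses: np.ndarray, eog_signals: np.ndarray
) -> set[int]:
    """For each EOG channel, the source with maximal |Pearson r| (de-duplicated).

    Ties break to the lowest source index.  Zero-variance sources or EOG
    traces make the correlation undefined and raise a warning; such pairs are
    treated as correlation 0.
    """
    src = np.atleast_2d(np.asarray(source_timecourses, dtype=float))
    eog = np.atleast_2d(np.asarray(eog_signals, dtype=float))
    if src.shape[1] != eog.shape[1]:
        raise ValueError("source and EOG sample counts differ")
    src_c = src - src.mean(axis=1, keepdims=True)
    eog_c = eog - eog.mean(axis=1, keepdims=True)
    src_sd = np.sqrt((src_c**2).sum(axis=1))
    eog_sd = np.sqrt((eog_c**2).sum(axis=1))
    if np.any(src_sd == 0) or np.any(eog_sd == 0):
        warnings.warn("zero-variance input; correlations set to 0 for those pairs")
    denom = np.outer(src_sd, eog_sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (src_c @ eog_c.T) / denom, 0.0)
    return {int(np.argmax(np.abs(r[:, j]))) for j in range(eog.shape[0])}


def remove_components(
    recording: Recording,
    unmixing: np.ndarray,
    mixing: np.ndarray,
    indices: set[int] | list[int],
) -> Recording:
    """Project to sources, zero the listed components, reconstruct."""
    n_comp = unmixing.shape[0]
    idx = sorted(int(i) for i in indices)
    if any(i < 0 or i >= n_comp for i in idx):
        raise IndexError(f"component index out of range 0..{n_comp - 1}")
    sources = unmixing @ recording.data
    sources[idx, :] = 0.0
    return Recording(
        mixing @ sources, recording.fs_hz, list(recording.channel_labels), recording.events
    )
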