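"""Synthetic press-locked ErrP EEG.

The generator emulates the statistical structure the classifier and the
screening indices assume: 1000 Hz, the 35-channel montage with cerebellar
electrodes, epochs of -500..+500 ms around the press, an ERN-band negative
deflection at fronto-central / parietal / occipital leads 240-340 ms after
an erroneous press, and an opposite-polarity, larger cerebellar deflection
(the Pe dominating the cerebellar difference wave).  Component amplitudes
and latencies default to measured group statistics: Fz -2.4 a.u. @ 286 ms,
FCz -1.8 @ 305 ms, Cz -0.5 @ 241 ms, P4 -1.1 @ 321 ms, Oz -0.8 @ 296 ms,
cerebellar ERN -1 @ 338 ms and Pe +3.57 @ 345 ms.

Correct trials carry noise only; error trials add each component as a
Gaussian-windowed monophasic bump with per-trial latency jitter.  Background
noise is 1/f-coloured and spatially mixed across channels, so spatial
filtering has genuine common-mode structure to suppress.  The whole stream
is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from errpkit.errors import ConfigError
from errpkit.io import LABEL_CORRECT, LABEL_ERROR, EpochSet
from errpkit.montage import DEFAULT_MONTAGE


@dataclass
class ErpComponent:
    """One Gaussian-windowed ERP bump added to error trials.

    ``channels`` maps channel name -> gain; the signed ``amplitude`` (a.u.)
    encodes polarity.  ``width_ms`` is the full width at half maximum.
    Latency is jittered per trial (Gaussian, sd ``jitter_sd_ms``) and
    truncated so the bump stays inside the epoch.
    """

    name: str
    channels: dict[str, float]
    amplitude: float
    latency_ms: float
    width_ms: float
    jitter_sd_ms: float = 15.0

    @property
    def sigma_ms(self) -> float:
        return self.width_ms / 2.3548200450309493  # FWHM -> Gaussian sigma


def default_components() -> list[ErpComponent]:
    """ERN/Pe components calibrated to group-average peak statistics."""
    return [
        ErpComponent("ern_Fz", {"Fz": 1.0, "F3": 0.6, "F4": 0.6}, -2.4, 286.0, 80.0),
        ErpComponent("ern_FCz", {"FCz": 1.0, "FC3": 0.6, "FC4": 0.6}, -1.8, 305.0, 80.0),
        ErpComponent("ern_Cz", {"Cz": 1.0, "C3": 0.5, "C4": 0.5}, -0.5, 241.0, 80.0),
        ErpComponent("ern_P4", {"P4": 1.0, "Pz": 0.6, "P3": 0.5}, -1.1, 321.0, 80.0),
        ErpComponent("ern_Oz", {"Oz": 1.0, "O1": 0.6, "O2": 0.6}, -0.8, 296.0, 80.0),
        ErpComponent("ern_CB", {"CBZ": 1.0, "CB1": 0.7, "CB2": 0.7}, -1.0, 338.0, 80.0),
        ErpComponent("pe_CB", {"CBZ": 1.0, "CB1": 0.7, "CB2": 0.7}, 3.57, 345.0, 120.0),
    ]


@dataclass
class NoiseConfig:
    """Background noise model: 1/f^alpha sources, spatially mixed.

    ``mixing`` in [0, 1] blends the identity with a random orthogonal
    matrix (0 = independent channels, 1 = fully mixed); rows are re-normalised
    so each channel keeps standard deviation ``sd``.
    """

    exponent: float = 1.0
    mixing: float = 0.5
    sd: float = 1.0


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic subject.

    ``amplitude_scale`` multiplies every component (global SNR knob);
    ``cerebellar_scale`` additionally multiplies components whose gains touch
    only CB channels, so cohorts can vary cerebellar expression on its own.
    """

    montage: tuple[str, ...] = DEFAULT_MONTAGE
    fs: float = 1000.0
    n_trials: int = 300
    error_rate: float = 0.3
    components: list[ErpComponent] = field(default_factory=default_components)
    amplitude_scale: float = 1.0
    cerebellar_scale: float = 1.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    epoch_window: tuple[float, float] = (-0.5, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.error_rate < 1:
            raise ConfigError("error_rate must lie in (0, 1)")
        if self.fs <= 0 or self.n_trials < 1:
            raise ConfigError("fs and n_trials must be positive")
        t0, t1 = self.epoch_window
        for comp in self.components:
            if not t0 * 1e3 <= comp.latency_ms <= t1 * 1e3:
                raise ConfigError(f"component {comp.name} latency outside the epoch")
            for ch in comp.channels:
                if ch.lower() not in (m.lower() for m in self.montage):
                    raise ConfigError(f"component {comp.name} references unknown channel {ch}")


def _one_over_f_noise(rng: np.random.Generator, n_sources: int, n_samples: int, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise traces, sources x samples.

    Synthesized directly in the frequency domain: independent complex
    Gaussian Fourier coefficients shaped by f^(-alpha/2), zero DC.
    """
    n_bins = n_samples // 2 + 1
    spec = rng.standard_normal((n_sources, n_bins)) + 1j * rng.standard_normal((n_sources, n_bins))
    f = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    colored = np.fft.irfft(spec * gain, n=n_samples, axis=1)
    std = colored.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return colored / std


def _mixing_matrix(rng: np.random.Generator, n_channels: int, mixing: float) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n_channels, n_channels)))
    a = (1.0 - mixing) * np.eye(n_channels) + mixing * q
    norms = np.linalg.norm(a, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return a / norms


def _component_scale(comp: ErpComponent, cfg: GeneratorConfig) -> float:
    scale = cfg.amplitude_scale
    if all(ch.upper().startswith("CB") for ch in comp.channels):
        scale *= cfg.cerebellar_scale
    return scale


def generate_epochs(cfg: GeneratorConfig | None = None) -> tuple[EpochSet, pd.DataFrame]:
    """Draw one subject's press-locked epochs plus the ground-truth record.

    Returns ``(epochs, truth)``; ``truth`` has one row per trial with the
    label and each component's jittered latency (NaN on correct trials).
    Identical seeds reproduce both bit-exactly.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_ch = len(cfg.montage)
    t0, t1 = cfg.epoch_window
    n_s = int(round((t1 - t0) * cfg.fs))
    times_ms = (t0 + np.arange(n_s) / cfg.fs) * 1e3

    labels = np.where(rng.random(cfg.n_trials) < cfg.error_rate, LABEL_ERROR, LABEL_CORRECT).astype(object)
    mix = _mixing_matrix(rng, n_ch, cfg.noise.mixing)
    lower = [m.lower() for m in cfg.montage]

    sources = _one_over_f_noise(rng, cfg.n_trials * n_ch, n_s, cfg.noise.exponent)
    sources = sources.reshape(cfg.n_trials, n_ch, n_s).transpose(1, 0, 2).reshape(n_ch, -1)
    data = cfg.noise.sd * (mix @ sources)
    data = data.reshape(n_ch, cfg.n_trials, n_s).transpose(1, 0, 2).copy()
    truth_rows: list[dict] = []
    for t in range(cfg.n_trials):
        row: dict = {"label": labels[t]}
        for comp in cfg.components:
            lat = np.nan
            if labels[t] == LABEL_ERROR:
                lat = rng.normal(comp.latency_ms, comp.jitter_sd_ms)
                lat = float(np.clip(lat, t0 * 1e3 + comp.width_ms, t1 * 1e3 - comp.width_ms))
                bump = np.exp(-0.5 * ((times_ms - lat) / comp.sigma_ms) ** 2)
                amp = comp.amplitude * _component_scale(comp, cfg)
                for ch, gain in comp.channels.items():
                    data[t, lower.index(ch.lower())] += amp * gain * bump
            row[comp.name] = lat
        truth_rows.append(row)

    epochs = EpochSet(
        data=data,
        fs=cfg.fs,
        t0_offset=t0,
        labels=labels,
        channel_names=list(cfg.montage),
        subject_id=f"synth-{cfg.seed}",
    )
    return epochs, pd.DataFrame(truth_rows)


def cohort_base_config() -> GeneratorConfig:
    """Per-subject conditions for cohort (screening) studies.

    Session-scale recordings (450 trials) with background noise sd 2 a.u.
    and a sub-saturating global component scale keep both the Fisher
    screening index and the classifier in their sensitive ranges: the
    finite-sample Fisher noise floor sits safely below the 0.15 screening
    threshold, and balanced accuracy is not ceilinged, so between-subject
    differences in cerebellar expression remain measurable.
    """
    return GeneratorConfig(n_trials=450, noise=NoiseConfig(sd=2.0, mixing=0.25))


def focal_config(seed: int = 0) -> GeneratorConfig:
    """Conditions probing lead selection: a spatially confined signal.

    The discriminative components live on exactly four channels (FCz plus
    the cerebellar triplet) over spatially independent background noise, in
    a short session (120 trials).  With most leads carrying no signal and
    trials scarce, an all-channel spatial filter overfits chance covariance
    structure, so data-driven lead screening has something real to win.
    """
    components = [
        ErpComponent("ern_FCz", {"FCz": 1.0}, -1.8, 305.0, 80.0),
        ErpComponent("pe_CB", {"CBZ": 1.0, "CB1": 0.7, "CB2": 0.7}, 3.57, 345.0, 120.0),
    ]
    return GeneratorConfig(
        components=components,
        amplitude_scale=0.5,
        n_trials=120,
        noise=NoiseConfig(mixing=0.0),
        seed=seed,
    )


def generate_cohort(
    n_subjects: int,
    amplitude_scales: np.ndarray | None = None,
    cerebellar_scales: np.ndarray | None = None,
    base: GeneratorConfig | None = None,
    seed: int = 0,
) -> tuple[list[EpochSet], pd.DataFrame]:
    """A cohort of subjects differing in (cerebellar) signal scale.

    Defaults: session-scale subjects (see :func:`cohort_base_config`) at a
    common global component scale of 0.3 with the cerebellar scale swept
    linearly over [0, 2], so cerebellar expression drives the
    between-subject separability spread.  Subject streams are deterministic
    per (cohort seed, subject index).
    """
    if n_subjects < 3:
        raise ConfigError("a cohort needs >= 3 subjects")
    base = base or cohort_base_config()
    if amplitude_scales is None:
        amplitude_scales = np.full(n_subjects, 0.3)
    if cerebellar_scales is None:
        cerebellar_scales = np.linspace(0.0, 2.0, n_subjects)
    if len(amplitude_scales) != n_subjects or len(cerebellar_scales) != n_subjects:
        raise ConfigError("scale vectors must have one entry per subject")

    subjects, rows = [], []
    for i in range(n_subjects):
        cfg = replace(
            base,
            amplitude_scale=float(amplitude_scales[i]),
            cerebellar_scale=float(cerebellar_scales[i]),
            seed=int((seed * 1_000_003 + i) % 2**31),
        )
        epochs, _ = generate_epochs(cfg)
        epochs.subject_id = f"cohort{seed}-s{i:02d}"
        subjects.append(epochs)
        rows.append(
            {
                "subject": epochs.subject_id,
                "amplitude_scale": cfg.amplitude_scale,
                "cerebellar_scale": cfg.cerebellar_scale,
                "seed": cfg.seed,
            }
        )
    return subjects, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# continuous BrainVision export


def _format_marker(i: int, kind: str, desc: str, pos: int) -> str:
    return f"Mk{i}={kind},{desc},{pos},1,0"


def write_continuous(
    cfg: GeneratorConfig,
    path: str | Path,
    gap_s: float = 0.5,
    n_timeout: int = 0,
) -> Path:
    """Embed the generated epochs in a continuous BrainVision recording.

    Epochs are laid head-to-tail with silent gaps of ``gap_s`` seconds and a
    press marker at each trial's t = 0 sample, so ``read_continuous`` +
    ``epoch`` reconstructs the epoch set (up to float32 container rounding).
    ``n_timeout`` extra ``press_timeout`` markers are placed inside gaps.

    Returns the path of the ``.vhdr`` header (data and marker files are
    written alongside).
    """
    path = Path(path)
    if path.suffix.lower() != ".vhdr":
        path = path.with_suffix(".vhdr")
    path.parent.mkdir(parents=True, exist_ok=True)

    epochs, _ = generate_epochs(cfg)
    n_trials, n_ch, n_s = epochs.data.shape
    gap = int(round(gap_s * cfg.fs))
    total = gap + n_trials * (n_s + gap)
    signal = np.zeros((n_ch, total))
    markers: list[tuple[int, str, str]] = []  # (pos0, kind, desc)

    press_offset = int(round(-epochs.t0_offset * cfg.fs))
    for t in range(n_trials):
        s0 = gap + t * (n_s + gap)
        signal[:, s0 : s0 + n_s] = epochs.data[t]
        code = "press_error" if epochs.labels[t] == LABEL_ERROR else "press_correct"
        markers.append((s0 + press_offset, "Stimulus", code))
    rng = np.random.default_rng(cfg.seed + 1)
    for _ in range(n_timeout):
        trial = int(rng.integers(0, n_trials))
        markers.append((gap // 2 + trial * (n_s + gap), "Stimulus", "press_timeout"))
    markers.sort()

    base = path.stem
    eeg_path = path.with_suffix(".eeg")
    vmrk_path = path.with_suffix(".vmrk")
    signal.T.astype("<f4").tofile(eeg_path)

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        f"MarkerFile={base}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / cfg.fs:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    header += [f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(epochs.channel_names)]
    path.write_text("\n".join(header) + "\n", encoding="utf-8")

    marker_lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    marker_lines += [
        _format_marker(i + 2, kind, desc, pos + 1)  # BrainVision positions are 1-based
        for i, (pos, kind, desc) in enumerate(markers)
    ]
    vmrk_path.write_text("\n".join(marker_lines) + "\n", encoding="utf-8")
    return path
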