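"""DFT power spectra and length-invariant power-spectrum-moment features.

Each of the four indicator vectors of a sequence is discrete-Fourier
transformed, X[k] = sum_n x[n] exp(-2j*pi*k*n/N), and squared into a power
spectrum P[k] = |X[k]|^2.  Spectra of different-length sequences live on
different frequency grids, so they are summarized by fixed-dimension
power-spectrum moments (PSM) over the normalized frequency f = k/N.  The
per-base block is [T_b, m_1, ..., m_J] with

    T_b = (sum_{k=1}^{N-1} P_b[k]) / N          (normalized total AC power)
    m_1 = sum_k w_b[k] * f[k]                   (spectral centroid)
    m_j = signed j-th root of the j-th central   (spectral spread, skew, ...)
          moment  sum_k w_b[k] * (f[k] - m_1)**j,   j = 2..J

where the weights w_b[k] are the power over the *unique half* of the
spectrum, k = 1 .. floor(N/2), normalized to sum to one.  Restricting to
the half spectrum matters: a real signal has conjugate-symmetric DFT, so
P[k] = P[N-k], and any moment taken over the full range k = 1..N-1 is
pinned by that symmetry (the full-range centroid is exactly 1/2 for every
sequence, carrying no information).  Taking the j-th root keeps every
moment in normalized-frequency units and avoids the 0/0 of standardized
skewness on degenerate (point-mass) spectra; all moment entries lie in
[-1/2, 1/2].

The DC term k = 0 equals the squared base count and is excluded (its
information — composition — enters through T_b, since the total AC power
of a binary vector with c ones is c*(N-c)).  A base absent from the
sequence contributes an all-zero block.  The resulting vector has dimension
4*(J+1) regardless of sequence length, so Euclidean distances between
sequences of very different lengths are well defined.  The plain
non-central moment alternative (m_j = sum w f^j) remains available via
``kind="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import BASE_ORDER, IndicatorSet

DEFAULT_MOMENT_ORDER = 3


@dataclass(frozen=True)
class SpectrumSet:
    """Complex DFT vectors and power spectra of one record's indicators."""

    id: str
    n: int
    dft_A: np.ndarray
    dft_T: np.ndarray
    dft_G: np.ndarray
    dft_C: np.ndarray
    power_A: np.ndarray
    power_T: np.ndarray
    power_G: np.ndarray
    power_C: np.ndarray

    def dft(self, base: str) -> np.ndarray:
        return getattr(self, f"dft_{base.upper()}")

    def power(self, base: str) -> np.ndarray:
        return getattr(self, f"power_{base.upper()}")


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-dimension PSM descriptor: per base (A,T,G,C), [T_b, m_1..m_J]."""

    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.id!r}: non-finite feature values")


def dft(signal: np.ndarray) -> np.ndarray:
    """X[k] = sum_{n=0}^{N-1} x[n] e^{-2j pi k n / N}, computed by FFT."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size == 0:
        raise ValueError("dft requires a non-empty 1-D signal")
    return np.fft.fft(signal)


def power_spectrum(spec: np.ndarray) -> np.ndarray:
    """P[k] = |X[k]|^2 = Re^2 + Im^2, element-wise."""
    spec = np.asarray(spec)
    return spec.real**2 + spec.imag**2


def spectrum_set(ind: IndicatorSet) -> SpectrumSet:
    """DFT all four indicator vectors of one record."""
    dfts = {b: dft(v) for b, v in ind.vectors()}
    powers = {b: power_spectrum(dfts[b]) for b in BASE_ORDER}
    return SpectrumSet(
        id=ind.id,
        n=ind.n,
        dft_A=dfts["A"],
        dft_T=dfts["T"],
        dft_G=dfts["G"],
        dft_C=dfts["C"],
        power_A=powers["A"],
        power_T=powers["T"],
        power_G=powers["G"],
        power_C=powers["C"],
    )


def moments_from_power(
    power: np.ndarray,
    n: int,
    J: int,
    *,
    include_dc: bool = False,
    kind: str = "central",
) -> np.ndarray:
    """[T, m_1, ..., m_J] summary of one power spectrum.

    ``n`` is the sequence length defining the normalized frequency k/n.
    T is the total AC power over k = 1..n-1 divided by n.  The moments use
    the unique half of the spectrum, k = 1..floor(n/2): with
    ``kind="central"`` (default) m_1 is the spectral centroid and m_j for
    j >= 2 the signed j-th root of the j-th power-weighted central moment;
    ``kind="raw"`` gives plain moments m_j = sum w * f**j instead.  With
    ``include_dc`` the k = 0 bin joins both the total and the weights.
    """
    if J < 1:
        raise ValueError("moment order J must be >= 1")
    if n < 2:
        raise ValueError("moments require sequence length >= 2")
    if kind not in ("central", "raw"):
        raise ValueError(f"unknown moment kind {kind!r}")
    power = np.asarray(power, dtype=float)
    k0 = 0 if include_dc else 1
    out = np.zeros(J + 1)
    out[0] = power[k0:n].sum() / n
    p = power[k0 : n // 2 + 1]
    total = p.sum()
    if total > 0:
        w = p / total
        f = np.arange(k0, n // 2 + 1) / n
        if kind == "raw":
            for j in range(1, J + 1):
                out[j] = np.dot(w, f**j)
        else:
            mu = np.dot(w, f)
            out[1] = mu
            for j in range(2, J + 1):
                cm = np.dot(w, (f - mu) ** j)
                out[j] = np.sign(cm) * np.abs(cm) ** (1.0 / j)
    return out


def moment_features(
    spectra: SpectrumSet,
    J: int = DEFAULT_MOMENT_ORDER,
    *,
    include_dc: bool = False,
    kind: str = "central",
) -> FeatureVector:
    """PSM feature vector of one sequence: 4*(J+1) values, base order A,T,G,C."""
    blocks = [
        moments_from_power(
            spectra.power(b), spectra.n, J, include_dc=include_dc, kind=kind
        )
        for b in BASE_ORDER
    ]
    return FeatureVector(id=spectra.id, values=np.concatenate(blocks))


def feature_names(J: int = DEFAULT_MOMENT_ORDER) -> list[str]:
    """Column names matching the FeatureVector layout."""
    names = []
    for b in BASE_ORDER:
        names.append(f"T_{b}")
        names.extend(f"m{j}_{b}" for j in range(1, J + 1))
    return names
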