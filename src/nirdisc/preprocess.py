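"""Spectral preprocessing: SG smoothing, SNV, MSC, and their combinations.

Three primitives and the standard two-step combinations used in NIR
chemometrics:

* **SNV** (standard normal variate): each spectrum standardized to zero
  mean and unit standard deviation — removes per-sample multiplicative and
  additive scatter.
* **MSC** (multiplicative scatter correction): each spectrum regressed on a
  reference spectrum (the training-set mean), then the fitted offset and
  slope inverted: ``x_corr = (x - a) / b``.
* **SG** (Savitzky–Golay): sliding-window least-squares polynomial
  smoothing; boundaries handled by mirror padding.

Every stage obeys a strict fit-on-train / apply-on-test contract: the MSC
reference is estimated on the training fold only and reused unchanged on
the test fold, so no test information leaks into the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from nirdisc.spectra import SpectraSet

__all__ = [
    "PreprocessSpec",
    "FittedPreprocessor",
    "PreprocessError",
    "DegenerateSpectrumError",
    "snv_transform",
    "msc_fit",
    "msc_apply",
    "sg_smooth",
    "fit_apply_chain",
    "TREATMENTS",
]

_VALID_STEPS = ("SG", "SNV", "MSC")

#: Named treatments; combination names apply steps left to right.
TREATMENTS = {
    "none": (),
    "SG": ("SG",),
    "SNV": ("SNV",),
    "MSC": ("MSC",),
    "MSC+SG": ("MSC", "SG"),
    "SNV+SG": ("SNV", "SG"),
    "SNV+MSC": ("SNV", "MSC"),
}


class PreprocessError(ValueError):
    """Invalid preprocessing parameters."""


class DegenerateSpectrumError(ValueError):
    """A spectrum cannot be corrected (zero variance, or slope ~ 0 in MSC)."""


@dataclass(frozen=True)
class PreprocessSpec:
    """An ordered list of at most two distinct steps plus SG parameters.

    ``snv_ddof=1`` selects the sample (n-1) standard deviation in SNV; set
    0 to reproduce population-SD conventions.
    """

    steps: tuple[str, ...] = ()
    sg_window: int = 11
    sg_polyorder: int = 2
    snv_ddof: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        for s in self.steps:
            if s not in _VALID_STEPS:
                raise PreprocessError(f"unknown step {s!r}; valid: {_VALID_STEPS}")
        if len(self.steps) > 2:
            raise PreprocessError("at most two steps may be combined")
        if len(set(self.steps)) != len(self.steps):
            raise PreprocessError("repeated preprocessing step")
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise PreprocessError(f"sg_window must be odd and >= 3, got {self.sg_window}")
        if self.sg_polyorder >= self.sg_window:
            raise PreprocessError("sg_polyorder must be < sg_window")
        if self.snv_ddof not in (0, 1):
            raise PreprocessError("snv_ddof must be 0 or 1")

    @classmethod
    def from_name(cls, name: str, sg_window: int = 11, sg_polyorder: int = 2,
                  snv_ddof: int = 1) -> "PreprocessSpec":
        """Build the spec for a named treatment such as ``"SNV+MSC"``."""
        if name not in TREATMENTS:
            raise PreprocessError(
                f"unknown treatment {name!r}; valid: {sorted(TREATMENTS)}"
            )
        return cls(steps=TREATMENTS[name], sg_window=sg_window,
                   sg_polyorder=sg_polyorder, snv_ddof=snv_ddof)

    @property
    def name(self) -> str:
        for key, steps in TREATMENTS.items():
            if steps == self.steps:
                return key
        return "+".join(self.steps)


def snv_transform(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: ``(x - mean(x)) / sd(x)`` per spectrum."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise PreprocessError("SNV needs a spectrum of length >= 2")
    sd = x.std(axis=-1, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSpectrumError("constant spectrum has zero variance under SNV")
    return (x - x.mean(axis=-1, keepdims=True)) / sd


def msc_fit(train: SpectraSet | np.ndarray) -> np.ndarray:
    """MSC reference spectrum: the column mean of the training absorbance."""
    X = train.absorbance if isinstance(train, SpectraSet) else np.atleast_2d(train)
    if X.shape[0] < 1:
        raise PreprocessError("MSC needs at least one training spectrum")
    return X.mean(axis=0)


def msc_apply(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Correct spectra against a reference by inverting a per-spectrum
    affine fit.

    Each spectrum is modeled as ``x ~ a + b * reference`` (ordinary least
    squares); the output is ``(x - a) / b``.

    Raises
    ------
    DegenerateSpectrumError
        If a fitted slope magnitude falls below 1e-8 (the affine map is not
        invertible) or the reference is constant.
    """
    x = np.asarray(x, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if x.shape[-1] != reference.shape[0]:
        raise PreprocessError(
            f"spectrum length {x.shape[-1]} != reference length {reference.shape[0]}"
        )
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise DegenerateSpectrumError("MSC reference spectrum is constant")
    X = np.atleast_2d(x)
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-8):
        raise DegenerateSpectrumError(
            "MSC slope below 1e-8; spectrum cannot be corrected"
        )
    a = X.mean(axis=1) - b * reference.mean()
    out = (X - a[:, None]) / b[:, None]
    return out if x.ndim > 1 else out[0]


def sg_smooth(x: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Savitzky–Golay smoothing with mirror-padded boundaries.

    Each point is replaced by the centre value of a least-squares
    polynomial of degree ``polyorder`` fitted over ``window`` points; the
    spectrum is mirror-padded (reflection about the end point, end point
    not repeated) by ``(window-1)//2`` points so the output has the same
    length.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window < 3:
        raise PreprocessError(f"window must be odd and >= 3, got {window}")
    if window > x.shape[-1]:
        raise PreprocessError(
            f"window {window} exceeds spectrum length {x.shape[-1]}"
        )
    if polyorder >= window:
        raise PreprocessError("polyorder must be < window")
    return savgol_filter(x, window_length=window, polyorder=polyorder,
                         axis=-1, mode="mirror")


@dataclass
class FittedPreprocessor:
    """A preprocessing chain with its train-fold state frozen.

    ``msc_reference`` is present exactly when MSC is one of the steps; it
    is the mean training spectrum *after* any steps preceding MSC in the
    chain have been applied.
    """

    spec: PreprocessSpec
    msc_reference: Optional[np.ndarray] = None

    def transform(self, data: SpectraSet) -> SpectraSet:
        """Apply the frozen chain to a SpectraSet."""
        X = data.absorbance
        for step in self.spec.steps:
            try:
                if step == "SNV":
                    X = snv_transform(X, ddof=self.spec.snv_ddof)
                elif step == "MSC":
                    if self.msc_reference is None:
                        raise PreprocessError("MSC reference was never fitted")
                    X = msc_apply(X, self.msc_reference)
                elif step == "SG":
                    X = sg_smooth(X, self.spec.sg_window, self.spec.sg_polyorder)
            except DegenerateSpectrumError as exc:
                # re-raise with the first offending sample named
                raise DegenerateSpectrumError(
                    f"{step} failed on {data.sample_ids[_first_bad_row(X, step, self)]!r}: {exc}"
                ) from exc
        return data.with_absorbance(X)


def _first_bad_row(X: np.ndarray, step: str, fitted: "FittedPreprocessor") -> int:
    """Best-effort index of the sample that made a row-wise step fail."""
    for i, row in enumerate(np.atleast_2d(X)):
        try:
            if step == "SNV":
                snv_transform(row, ddof=fitted.spec.snv_ddof)
            elif step == "MSC" and fitted.msc_reference is not None:
                msc_apply(row, fitted.msc_reference)
        except DegenerateSpectrumError:
            return i
    return 0


def fit_apply_chain(
    spec: PreprocessSpec, train: SpectraSet, test: SpectraSet
) -> tuple[SpectraSet, SpectraSet, FittedPreprocessor]:
    """Fit the chain on the training fold and apply it to both folds.

    Steps run in the listed order.  When MSC appears, its reference is the
    mean of the training spectra at that point in the chain and is reused
    verbatim on the test fold (no leakage).
    """
    if not np.array_equal(train.wavenumbers, test.wavenumbers):
        raise PreprocessError("train and test must share the wavenumber grid")
    Xtr, Xte = train.absorbance, test.absorbance
    reference = None
    for step in spec.steps:
        if step == "SNV":
            Xtr = snv_transform(Xtr, ddof=spec.snv_ddof)
            Xte = snv_transform(Xte, ddof=spec.snv_ddof)
        elif step == "MSC":
            reference = msc_fit(Xtr)
            Xtr = msc_apply(Xtr, reference)
            Xte = msc_apply(Xte, reference)
        elif step == "SG":
            Xtr = sg_smooth(Xtr, spec.sg_window, spec.sg_polyorder)
            Xte = sg_smooth(Xte, spec.sg_window, spec.sg_polyorder)
    fitted = FittedPreprocessor(spec=spec, msc_reference=reference)
    return train.with_absorbance(Xtr), test.with_absorbance(Xte), fitted
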