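"""Common Model/Results interface for the age predictors.

Every predictor follows the same two-object pattern: a model is built from
training data, ``fit()`` returns a results object that carries the estimated
parameters, and the results object is the thing that predicts.  Prediction is
deterministic given the fitted parameters.
"""

from __future__ import annotations

import abc

import numpy as np

__all__ = ["AgeModel", "AgeModelResults", "UnsupportedOperationError", "FitError"]


class FitError(ValueError):
    """Raised when a model cannot be fitted to the given training data."""


class UnsupportedOperationError(TypeError):
    """Raised when an operation (e.g. embed) is not defined for a predictor."""


class AgeModel(abc.ABC):
    """Abstract age-prediction model holding its training data."""

    #: "asi" for models fit on the extracted stiffness index, "waveform" for
    #: models fit on raw pulses.
    input_kind: str = "asi"

    def __init__(self, endog, exog=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = None if exog is None else np.asarray(exog, dtype=float)
        if self.endog.size == 0:
            raise FitError("empty training set")

    @abc.abstractmethod
    def fit(self, **kwargs) -> "AgeModelResults":
        ...


class AgeModelResults:
    """Fitted predictor: parameters plus deterministic prediction."""

    kind: str = "base"

    def __init__(self, model: AgeModel, params: dict):
        self.model = model
        self.params = params

    def predict(self, exog=None) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def embed(self, exog=None):
        raise UnsupportedOperationError(
            f"{self.kind!r} predictors do not expose embeddings")

    def summary(self) -> str:
        lines = [f"{self.__class__.__name__} (kind={self.kind})",
                 "-" * 40]
        for key, val in self.params.items():
            if isinstance(val, (int, float, np.floating)):
                lines.append(f"{key:>24s}: {val:.6g}")
            elif isinstance(val, np.ndarray) and val.size <= 8:
                lines.append(f"{key:>24s}: {np.array2string(val, precision=4)}")
            else:
                shape = getattr(val, "shape", None)
                lines.append(f"{key:>24s}: <{type(val).__name__}"
                             + (f" shape={shape}>" if shape is not None else ">"))
        return "\n".join(lines)
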