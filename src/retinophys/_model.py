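"""Lightweight Model / Results machinery shared by all fit classes.

Every estimator in the package follows the same two-object pattern: a
Model is constructed from data plus fixed settings, ``fit()`` performs
the estimation and returns a Results object carrying point estimates,
standard errors where the estimator provides them, diagnostics, and a
``summary()`` table.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = ["Model", "Results", "minimize_quietly"]


def minimize_quietly(residual, params, **kwargs):
    """lmfit.minimize with the covariance RuntimeWarnings silenced.

    Perfect (zero-residual) fits make the covariance singular and lmfit
    warns while computing standard errors; the NaN stderr that results
    is the correct report for that case.
    """
    import warnings

    import lmfit

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return lmfit.minimize(residual, params, **kwargs)


class Model:
    """Base class: hold data + settings, estimate on ``fit()``."""

    def fit(self) -> "Results":  # pragma: no cover - abstract
        raise NotImplementedError


class Results:
    """Container for fitted parameters and diagnostics.

    Parameters
    ----------
    model : Model
        The model instance that produced these results.
    params : dict
        Point estimates, by name.
    bse : dict, optional
        Standard errors of the estimates, by name (NaN when the
        estimator does not provide one).
    diagnostics : dict, optional
        Scalar diagnostics (rms residual, n observations, flags ...).
    """

    def __init__(self, model: Model, params: Dict[str, float],
                 bse: Optional[Dict[str, float]] = None,
                 diagnostics: Optional[Dict] = None):
        self.model = model
        self.params = dict(params)
        self.bse = dict(bse) if bse else {k: np.nan for k in self.params}
        self.diagnostics = dict(diagnostics) if diagnostics else {}

    def params_frame(self) -> pd.DataFrame:
        names = list(self.params)
        return pd.DataFrame(
            {"estimate": [self.params[k] for k in names],
             "std_err": [self.bse.get(k, np.nan) for k in names]},
            index=pd.Index(names, name="parameter"),
        )

    def summary(self) -> str:
        title = type(self).__name__
        lines = [title, "=" * len(title)]
        lines.append(self.params_frame().to_string(float_format="%.6g"))
        if self.diagnostics:
            lines.append("-" * len(title))
            for k, v in self.diagnostics.items():
                if isinstance(v, float):
                    lines.append(f"{k}: {v:.6g}")
                else:
                    lines.append(f"{k}: {v}")
        return "\n".join(lines)

    def __repr__(self):
        pieces = ", ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                           for k, v in self.params.items())
        return f"<{type(self).__name__} {pieces}>"
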