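"""PCA-based retention of climate questionnaire items.

The climate items live on heterogeneous scales (0-100 scores vs a violence
count), so the PCA runs on the correlation matrix (all variables
standardised).  An item is retained when the absolute value of its loading —
its correlation with one of the first two principal components — strictly
exceeds a threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["SelectionResult", "pca_select"]


@dataclass
class SelectionResult:
    retained: list
    loadings: pd.DataFrame  # variable x component correlation loadings
    variance_explained_first2: float

    def to_frame(self) -> pd.DataFrame:
        out = self.loadings.copy()
        out["retained"] = [v in self.retained for v in out.index]
        return out


def pca_select(
    climate: pd.DataFrame, n_components: int = 2, threshold: float = 0.5
) -> SelectionResult:
    """Select items loading strictly above ``threshold`` on the first
    ``n_components`` components of the correlation-matrix PCA.

    Rows with any missing value are dropped listwise.  A constant column has
    no defined correlation and raises :class:`ValidationError` naming it.
    Loadings are ``eigenvector * sqrt(eigenvalue)``, i.e. the correlations
    between each standardised variable and the component scores; their sign
    is indeterminate and irrelevant to retention.
    """
    X = climate.apply(pd.to_numeric, errors="coerce").dropna(axis=0, how="any")
    if X.shape[1] < 3:
        raise ValidationError("need at least 3 variables")
    if X.shape[0] < n_components + 1:
        raise ValidationError("need at least n_components + 1 complete rows")
    sds = X.std(ddof=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise ValidationError(f"constant variable(s) with undefined correlation: {constant}")
    R = np.corrcoef(X.to_numpy(float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lead = eigval[:n_components]
    load = eigvec[:, :n_components] * np.sqrt(np.clip(lead, 0, None))
    loadings = pd.DataFrame(
        load, index=X.columns, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    retained = [v for v in X.columns if np.max(np.abs(loadings.loc[v])) > threshold]
    return SelectionResult(
        retained=retained,
        loadings=loadings,
        variance_explained_first2=float(lead.sum() / eigval.sum()),
    )
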