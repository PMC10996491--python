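"""Epithelial gating and probabilistic basal/luminal/intermediate identity.

The lineage model is a 3-component full-covariance bivariate Gaussian
mixture over per-cell (basal score, luminal score) pairs. The three
fitted components are mapped to labels deterministically from their
means: the component with the largest (luminal mean - basal mean) is
luminal, the one with the largest (basal mean - luminal mean) is basal,
and the remaining component — high in both marker programs — is the
intermediate state. Posterior responsibilities under the mixture give
each cell its (p_basal, p_luminal, p_intermediate) triple; the hard
assignment is the most probable type, with ties broken toward
intermediate so the rare state is flagged for review rather than
silently absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "EpithelialGate",
    "gate_epithelial",
    "LineageMixture",
    "LineageMixtureResults",
    "LineagePosterior",
    "fit_lineage_gmm",
    "lineage_posteriors",
]

LABELS = ("basal", "luminal", "intermediate")


@dataclass
class EpithelialGate:
    """Result of the Epcam-based epithelial cluster gate."""

    cluster_fraction: pd.Series  # per cluster, fraction of Epcam+ cells
    flagged: pd.Series  # per cluster, fraction >= threshold
    subtype: pd.Series  # per cell in flagged clusters, argmax signature
    threshold: float

    @property
    def retained_cells(self) -> pd.Index:
        return self.subtype.index


def gate_epithelial(
    cluster_labels: pd.Series,
    epcam_positive: pd.Series,
    signature_scores: pd.DataFrame,
    subtypes: Sequence[str] = ("basal", "L1", "L2", "L3"),
    fraction_threshold: float = 0.50,
) -> EpithelialGate:
    """Flag epithelial clusters and assign subtypes within them.

    A cluster is flagged epithelial when at least ``fraction_threshold``
    of its cells are Epcam-positive. Within flagged clusters each cell's
    subtype is the argmax over its signature scores; only those cells
    are retained downstream.
    """
    missing = [s for s in subtypes if s not in signature_scores.columns]
    if missing:
        raise ValueError(f"missing signature score set(s): {missing}")
    epcam_positive = epcam_positive.reindex(cluster_labels.index)
    frac = epcam_positive.astype(float).groupby(cluster_labels).mean()
    flagged = frac >= fraction_threshold
    in_flagged = cluster_labels.map(flagged).fillna(False).astype(bool)
    cells = cluster_labels.index[in_flagged]
    scores = signature_scores.loc[cells, list(subtypes)]
    subtype = scores.idxmax(axis=1)
    subtype.name = "subtype"
    return EpithelialGate(
        cluster_fraction=frac.rename("epcam_fraction"),
        flagged=flagged.rename("epithelial"),
        subtype=subtype,
        threshold=fraction_threshold,
    )


@dataclass
class LineagePosterior:
    """Per-cell lineage probabilities and the hard assignment."""

    probabilities: pd.DataFrame  # columns p_basal, p_luminal, p_intermediate
    labels: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out["label"] = self.labels
        return out


class LineageMixture:
    """3-component bivariate Gaussian mixture over lineage marker scores.

    Parameters
    ----------
    basal_score, luminal_score
        Per-cell marker-program scores on a common cell index (any
        array-like of equal length also works).
    """

    def __init__(self, basal_score, luminal_score):
        basal = pd.Series(basal_score)
        luminal = pd.Series(luminal_score)
        if len(basal) != len(luminal):
            raise ValueError("score vectors differ in length")
        X = np.column_stack([basal.to_numpy(dtype=float), luminal.to_numpy(dtype=float)])
        if not np.all(np.isfinite(X)):
            raise ValueError("scores must be finite")
        if len(X) < 30:
            raise ValueError("need at least 30 cells to fit the lineage mixture")
        self.endog = X
        self.cells = basal.index if isinstance(basal_score, pd.Series) else pd.RangeIndex(len(X))

    @classmethod
    def from_dataframe(
        cls, scores: pd.DataFrame, basal_col: str = "basal", luminal_col: str = "luminal"
    ) -> "LineageMixture":
        return cls(scores[basal_col], scores[luminal_col])

    def fit(self, seed: int = 0, n_init: int = 10, reg_covar: float = 1e-6) -> "LineageMixtureResults":
        """EM fit (k-means init, best of ``n_init`` by log-likelihood)."""
        gmm = GaussianMixture(
            n_components=3,
            covariance_type="full",
            n_init=n_init,
            init_params="kmeans",
            reg_covar=reg_covar,
            random_state=seed,
        )
        try:
            gmm.fit(self.endog)
        except Exception:
            # one retry with a stronger diagonal regularization
            gmm.set_params(reg_covar=max(reg_covar, 1e-4))
            gmm.fit(self.endog)
        if not gmm.converged_:
            raise RuntimeError("EM did not converge")
        return LineageMixtureResults(self, gmm)


def _label_components(means: np.ndarray) -> dict[int, str]:
    """Deterministic component -> label map from mean contrasts.

    luminal = argmax(luminal mean - basal mean); basal = argmax of the
    opposite contrast among the remaining components; the leftover
    component is intermediate.
    """
    contrast = means[:, 1] - means[:, 0]  # luminal minus basal
    luminal = int(np.argmax(contrast))
    rest = [k for k in range(3) if k != luminal]
    basal = rest[int(np.argmax(-contrast[rest]))]
    intermediate = next(k for k in range(3) if k not in (luminal, basal))
    return {basal: "basal", luminal: "luminal", intermediate: "intermediate"}


class LineageMixtureResults:
    """Fitted lineage mixture: parameters, label map, posteriors."""

    def __init__(self, model: LineageMixture, gmm: GaussianMixture):
        self.model = model
        self._gmm = gmm
        self.component_labels = _label_components(gmm.means_)
        order = {lab: k for k, lab in self.component_labels.items()}
        self.means = pd.DataFrame(
            gmm.means_[[order[lab] for lab in LABELS]],
            index=list(LABELS),
            columns=["basal_score", "luminal_score"],
        )
        self.covariances = {lab: gmm.covariances_[order[lab]] for lab in LABELS}
        self.weights = pd.Series(
            gmm.weights_[[order[lab] for lab in LABELS]], index=list(LABELS), name="weight"
        )
        self.log_likelihood = float(gmm.score(model.endog) * len(model.endog))

    def posterior(self, basal_score=None, luminal_score=None) -> LineagePosterior:
        """Lineage posteriors for new scores (default: the training cells).

        The hard label is the argmax probability; exact ties involving
        the intermediate component resolve to intermediate.
        """
        if basal_score is None:
            X = self.model.endog
            index = self.model.cells
        else:
            basal = pd.Series(basal_score)
            luminal = pd.Series(luminal_score)
            X = np.column_stack([basal.to_numpy(float), luminal.to_numpy(float)])
            if not np.all(np.isfinite(X)):
                raise ValueError("scores must be finite")
            index = basal.index if isinstance(basal_score, pd.Series) else pd.RangeIndex(len(X))
        resp = self._gmm.predict_proba(X)
        prob = pd.DataFrame(index=index, columns=[f"p_{lab}" for lab in LABELS], dtype=float)
        for k, lab in self.component_labels.items():
            prob[f"p_{lab}"] = resp[:, k]
        arr = prob.to_numpy()
        tie_with_im = arr[:, 2] >= arr.max(axis=1) - 1e-12
        hard = np.array(LABELS)[arr.argmax(axis=1)]
        hard[tie_with_im] = "intermediate"
        labels = pd.Series(hard, index=index, name="label")
        return LineagePosterior(probabilities=prob, labels=labels)

    def summary(self) -> str:
        lines = ["Lineage Gaussian mixture (3 components, full covariance)", ""]
        lines.append(f"{'component':<14}{'weight':>8}{'basal mean':>12}{'luminal mean':>14}")
        for lab in LABELS:
            mu = self.means.loc[lab]
            lines.append(
                f"{lab:<14}{self.weights[lab]:>8.3f}{mu['basal_score']:>12.3f}{mu['luminal_score']:>14.3f}"
            )
        lines.append("")
        lines.append(f"log-likelihood: {self.log_likelihood:.2f}   n = {len(self.model.endog)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "means": {lab: self.means.loc[lab].tolist() for lab in LABELS},
            "covariances": {lab: self.covariances[lab].tolist() for lab in LABELS},
            "weights": self.weights.to_dict(),
            "log_likelihood": self.log_likelihood,
        }


def fit_lineage_gmm(basal_score, luminal_score, seed: int = 0) -> LineageMixtureResults:
    """Convenience wrapper: fit the lineage mixture on two score vectors."""
    return LineageMixture(basal_score, luminal_score).fit(seed=seed)


def lineage_posteriors(results: LineageMixtureResults, basal_score=None, luminal_score=None) -> LineagePosterior:
    """Convenience wrapper around :meth:`LineageMixtureResults.posterior`."""
    return results.posterior(basal_score, luminal_score)
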