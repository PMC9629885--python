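"""Small-sample AIC model comparison for the mono- vs biphasic fits.

The two candidate fits are compared with the Gaussian AICc (the
small-sample-adjusted Akaike information criterion),

    AICc = n*ln(rss/n) + 2k + 2k(k+1)/(n - k - 1),

with the residual variance profiled out so that additive constants shared
by both models cancel.  Akaike weights turn the AICc difference into model
probabilities; the model with probability strictly above 50% is selected
(an exact tie goes to the monophasic model by parsimony).  Whatever the
selection, the biphasic fit also yields the geometric-mean dissociation
constant K_D(geo) = sqrt(K_D1*K_D2) and the amplitude-normalised phase
proportions, which are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fit import BindingFitResults
from .models import BindingParamsBi

__all__ = ["ModelChoice", "aicc", "model_probabilities", "choose_model"]


def aicc(n: int, k: int, rss: float) -> float:
    """Gaussian AICc up to an additive constant shared by both models.

    Requires ``n > k + 1`` for the small-sample correction.  ``rss = 0``
    (an exact fit) maps to ``-inf``; callers compare such values by
    parsimony.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1} (curve too short)")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0:
        return float("-inf")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def model_probabilities(aicc_mono: float, aicc_bi: float) -> tuple[float, float]:
    """Akaike weights ``exp(-delta_i/2) / sum_j exp(-delta_j/2)``.

    Handles ``-inf`` inputs (exact fits): a lone ``-inf`` takes probability
    one; a double ``-inf`` is an exact tie, (0.5, 0.5).
    """
    if np.isnan(aicc_mono) or np.isnan(aicc_bi):
        raise ValueError("AICc values must not be NaN")
    if np.isneginf(aicc_mono) and np.isneginf(aicc_bi):
        return 0.5, 0.5
    if np.isneginf(aicc_mono):
        return 1.0, 0.0
    if np.isneginf(aicc_bi):
        return 0.0, 1.0
    best = min(aicc_mono, aicc_bi)
    w = np.exp([-(aicc_mono - best) / 2.0, -(aicc_bi - best) / 2.0])
    w = w / w.sum()
    return float(w[0]), float(w[1])


@dataclass(frozen=True)
class ModelChoice:
    """Outcome of the mono- vs biphasic comparison for one curve.

    ``kd_report`` is the single practical affinity measurement carried to
    reporting: the monophasic K_D when the monophasic model is selected,
    else K_D(geo).  The biphasic summaries (``kd_geo``, proportions) are
    populated from the biphasic fit regardless of the selection.
    """

    aicc_mono: float
    aicc_bi: float
    prob_mono: float
    prob_bi: float
    selected: str  # {"monophasic", "biphasic", "unevaluable"}
    kd_report: float
    kd_geo: float
    proportion_high: float
    proportion_low: float
    kd_mono: float
    kd1: float
    kd2: float
    degenerate: bool = False


def choose_model(mono_fit: BindingFitResults, bi_fit: BindingFitResults) -> ModelChoice:
    """Select the best-supported model and assemble the reporting summary.

    When only one fit converged, that fit is selected with a degenerate
    flag; when neither converged the sample is marked unevaluable (the
    mono K_D is still carried as ``kd_report`` so flagged samples remain
    in the output, as the study retained its failing time points).
    """
    if not isinstance(bi_fit.params, BindingParamsBi):
        raise TypeError("bi_fit must be a biphasic fit")
    bp = bi_fit.params
    kd_geo = bp.kd_geo
    prop_high = bp.proportion_high
    kd_mono = mono_fit.params.kd

    if mono_fit.converged and bi_fit.converged:
        a_mono = aicc(mono_fit.n, mono_fit.k, mono_fit.rss)
        a_bi = aicc(bi_fit.n, bi_fit.k, bi_fit.rss)
        p_mono, p_bi = model_probabilities(a_mono, a_bi)
        # strict >50% required for the biphasic call; ties go to parsimony
        selected = "biphasic" if p_bi > 0.5 else "monophasic"
        degenerate = bi_fit.degenerate_phases
    elif mono_fit.converged or bi_fit.converged:
        selected = "monophasic" if mono_fit.converged else "biphasic"
        a_mono = a_bi = float("nan")
        p_mono, p_bi = (1.0, 0.0) if mono_fit.converged else (0.0, 1.0)
        degenerate = True
    else:
        selected = "unevaluable"
        a_mono = a_bi = float("nan")
        p_mono = p_bi = float("nan")
        degenerate = True

    kd_report = kd_mono if selected in ("monophasic", "unevaluable") else kd_geo
    return ModelChoice(
        aicc_mono=a_mono,
        aicc_bi=a_bi,
        prob_mono=p_mono,
        prob_bi=p_bi,
        selected=selected,
        kd_report=kd_report,
        kd_geo=kd_geo,
        proportion_high=prop_high,
        proportion_low=1.0 - prop_high,
        kd_mono=kd_mono,
        kd1=bp.kd1,
        kd2=bp.kd2,
        degenerate=degenerate,
    )
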