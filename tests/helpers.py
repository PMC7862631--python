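"""Shared covariate-free model sets for analytic kernel checks."""

import math

from shrubipm.ipm_core import SpeciesModelSet
from shrubipm.vital_rates import VitalRateModel


def _logit(p):
    return math.log(p / (1 - p))


def toy_model_set(surv_p=0.7, repro_p=1e-12, fec=1.0, growth_incr=0.0,
                  growth_sd=0.05, recruit_mean=0.5, recruit_sd=0.3,
                  extra=None):
    """A model set with constant (size- and covariate-free) rates, apart from
    optional `extra` terms, so kernel eigenvalues have closed forms."""
    extra = extra or {}

    def model(rate, family, intercept, **kw):
        c = {"intercept": intercept, "size": 0.0}
        if rate == "survival":
            c["size2"] = 0.0
        c.update(extra.get(rate, {}))
        terms = tuple(t for t in c if t not in ("intercept", "size", "size2"))
        return VitalRateModel(species="HS", rate=rate, family=family,
                              terms=terms, coefficients=c, **kw)

    return SpeciesModelSet(
        species="HS",
        survival=model("survival", "binomial", _logit(surv_p)),
        growth=model("growth", "gaussian", growth_incr, sigma_resid=growth_sd),
        reproduction=model("reproduction", "binomial", _logit(repro_p)),
        fecundity=model("fecundity", "poisson", math.log(fec)),
        recruit_log_mean=recruit_mean,
        recruit_log_sd=recruit_sd,
    )
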