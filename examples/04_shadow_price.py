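"""From fitted coefficients to pounds: the compensating income variation.

Takes a coefficient pair (alcohol effect on affect, log-income effect on
affect) with its covariance, transforms it into the income fraction tau
that offsets one extra gram/day, attaches a delta-method interval,
monetizes it against an age-band income/tax table, and pools four
per-equation prices into one headline figure.
"""

import numpy as np

from affectprice import (
    CoefPair,
    civ_result,
    convert_consumption_equivalents,
    pool_civ,
)
from affectprice.pricing import DEFAULT_INCOME_TAX_TABLE

# a coefficient pair of the magnitude seen in large-cohort affect equations
pair = CoefPair(beta_AC=0.001, beta_lnY=-0.157,
                cov=np.diag([1.3e-4**2, 1.64e-2**2]))
res = civ_result(pair, DEFAULT_INCOME_TAX_TABLE, source="example")
print(f"tau = {100*res.tau:.3f}% of income per extra gram/day (se {100*res.se_tau:.3f}%)")
print(f"monetized against the (placeholder) income/tax table: £{res.civ_pounds:.2f} per year")

# pooling four per-equation prices, as reported across two outcomes x two designs
pooled = pool_civ([204.89, 231.26, 178.04, 222.03])
print(f"\npooled price: £{pooled.mean:.2f} per gram/day "
      f"(95% CI £{pooled.ci95[0]:.2f} to £{pooled.ci95[1]:.2f})")

beer = convert_consumption_equivalents(pooled.mean, grams_per_serving=20.45, servings_per_week=1)
print(f"one pint of beer (20.45 g ethanol) per week ≈ £{beer:.2f} of annual household income")
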