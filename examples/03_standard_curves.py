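"""Standard curves: slope -> percent amplification efficiency, range trimming.

A serial 10-fold dilution of template is refit by ordinary least squares of
mean Cq on log10(amount); the slope gives the efficiency via
E = (10^(-1/slope) - 1) x 100.  When the dilute end drops out or the
concentrated end saturates, select_linear_range trims to the best-fitting
contiguous sub-range.
"""

from refstab import (
    DilutionPoint,
    efficiency_from_slope,
    fit_standard_curve,
    select_linear_range,
    simulate_dilution_series,
)

# Noiseless series from known parameters refits them exactly.
amounts = [100.0 / 10**k for k in range(9)]  # 100 ng down to 1 pg
series = simulate_dilution_series("HSPCB", true_slope=-3.250,
                                  true_intercept=20.09, amounts=amounts)
fit = fit_standard_curve(series)
print(f"{fit.gene_id}: slope {fit.slope:.3f}, intercept {fit.intercept:.2f}, "
      f"R^2 {fit.r_squared:.3f}, efficiency {fit.efficiency_percent:.1f}%")

# The formula alone, for a few published calibration slopes:
for slope in (-3.250, -3.411, -3.582):
    print(f"slope {slope:+.3f} -> efficiency {efficiency_from_slope(slope):.1f}%")

# A series that saturates at the top: the 100 ng point barely moves from
# 10 ng, and the range search drops it.
sat = [DilutionPoint("SAT", a, (20.0 + 3.3 * k,))
       for k, a in enumerate(amounts[1:5], start=1)]
sat.append(DilutionPoint("SAT", 100.0, (20.0 + 3.3 - 0.3,)))
winner, trimmed = select_linear_range(sat, min_points=4)
print(f"saturated series: kept {trimmed.n_points} points, range "
      f"{trimmed.range_used[0]:g}-{trimmed.range_used[1]:g} ng, "
      f"slope {trimmed.slope:.3f}, R^2 {trimmed.r_squared:.5f}")
# Efficiency near 100% means close-to-perfect doubling each cycle; the
# trimmed range excludes the saturated 100 ng point.
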