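"""Apparent GCV of environmental variance versus scale-effect strength.

GCV is exactly linear in the strength r and approximately 2*r*CV for small
CV. Even a weak scale effect (r = 0.3) at CV = 0.15 yields GCV ~ 0.09;
the full-strength effect reaches ~0.31 -- values routinely interpreted as
genetic heterogeneity of environmental variance.
"""

from varscale import ScenarioConfig, run_scenario, small_cv_gcv_limit

cv = 0.15
print(f"CV = {cv}   (h2 fixed at 0.30; GCV is h2-invariant)")
print(f"{'r':>5}  {'mean GCV':>9}  {'2*r*CV':>7}")
for r in (0.05, 0.30, 0.60, 1.00):
    res = run_scenario(
        ScenarioConfig(cv=cv, h2=0.30, r=r, n_individuals=50_000,
                       n_replicates=5, seed=11)
    )
    limit = small_cv_gcv_limit(cv, r)
    print(f"{r:>5.2f}  {res.mean_gcv:>9.4f}  {limit.value:>7.4f}")
print("\nthe small-CV limit understates GCV slightly at CV = 0.15;")
print("the quadrature oracle (varscale.quadrature_gcv) is exact.")
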