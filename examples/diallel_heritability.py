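"""Half-diallel combining-ability analysis on simulated phenotypes.

Simulates an eight-parent half-diallel (28 crosses, 2 replicate plots,
15 roots per plot) with known GCA/SCA/error variances, runs the Griffing
Method IV, Model I analysis, and prints the estimated components and
heritabilities next to the generating truth.
"""

from taproot.diallel import DiallelConfig, DiallelTable, analyze
from taproot.synth import DiallelSimParams, simulate_diallel

params = DiallelSimParams(
    p=8, r=2, n_roots=15, mu=180.0, var_gca=25.0, var_sca=5.0, var_err=50.0, seed=4
)
table = simulate_diallel(params)
print(f"simulated {len(table)} roots over {params.p * (params.p - 1) // 2} crosses")

result = analyze(DiallelTable(table), DiallelConfig(p=8, r=2, F=1.0))
print(f"MS_GCA = {result.ms_gca:8.2f}   MS_SCA = {result.ms_sca:6.2f}   "
      f"df = {result.df_gca}, {result.df_sca}")
print(f"V_GCA  = {result.v_gca:8.2f}   (simulated 25.0)")
print(f"V_SCA  = {result.v_sca:8.2f}   (simulated  5.0)")
print(f"V_eps  = {result.v_eps_root:8.2f}   per-root basis (simulated 50.0)")
print(f"V_A    = {result.v_a:8.2f}   V_D = {result.v_d:6.2f}   (F = 1)")
print(f"H²     = {result.H2:8.2f}   h² = {result.h2:6.2f}   Baker's ratio = {result.bakers_ratio:.2f}")
print("GCA effects per parent (sum to zero):")
print(result.gca_effects.round(2).to_string())
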