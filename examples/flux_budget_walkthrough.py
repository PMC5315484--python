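"""Evaluate the full carbon/nitrogen flux budget for one cell.

K. veneficum in a bright, nutrient-replete, prey-free environment: the cell
runs on photosynthesis and dissolved nitrogen alone, and nitrogen limits
synthesis (J_tot = c_CN * N_syn), leaving excess carbon to be excreted.
"""

from mixotroph import Environment, K_VENEFICUM, compute_budget

env = Environment(X_L=400.0, X_N=500.0, X_F=0.0)
budget = compute_budget(K_VENEFICUM.traits, env)

print(f"traits:           {K_VENEFICUM.traits}")
print(f"environment:      {env}")
print(f"photosynthesis    J_L   = {budget.J_L:.3e} ugC/d")
print(f"nitrogen uptake   J_N   = {budget.J_N:.3e} ugN/d  (rho = {budget.rho:.2f})")
print(f"basal respiration J_R   = {budget.J_R:.3e} ugC/d")
print(f"synthesis         J_tot = {budget.J_tot:.3e} ugC/d (C_syn = {budget.C_syn:.3e})")
print(f"excreted carbon         = {budget.excreted_C:.3e} ugC/d")
print(f"net growth        g     = {budget.g:.4f} /d")
print()
print("J_tot equals the nitrogen-limited branch c_CN*N_syn; the cell grows at")
print("~0.22/d and sheds the carbon it cannot match with nitrogen.")
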