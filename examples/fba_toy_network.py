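"""Flux balance analysis on the toy hepatic ammonia-detoxification network.

Builds the small hand-verifiable hepatocyte network, maximizes ammonia
uptake and prints the resulting exchange fluxes, then repeats the solve
with the urea cycle blocked and glutamine/alanine capacity raised fourfold
(the urea-cycle-disorder condition).
"""

from hepaflux import fba
from hepaflux.toyliver import AMMONIA_OBJECTIVE, make_ammonia_network

net = make_ammonia_network()
sol = fba(net, AMMONIA_OBJECTIVE)
print("Healthy hepatocyte (maximize ammonia uptake):")
for rid in ("EX_nh3", "EX_urea", "EX_gln", "EX_ala"):
    print(f"  {rid:8s} {sol[rid]:.4f} µmol/L/min")
# uptake 0.163 splits into urea (2 N each), glutamine (2 N) and alanine (1 N)

ucd = fba(net, AMMONIA_OBJECTIVE,
          {"UC": 0.0, "EX_gln": (0.032, 0.032), "EX_ala": (0.008, 0.008)})
print("\nUrea cycle blocked, fourfold glutamine/alanine capacity:")
for rid in ("EX_nh3", "EX_urea", "EX_gln", "EX_ala"):
    print(f"  {rid:8s} {ucd[rid]:.4f} µmol/L/min")
print("\nWithout the urea cycle the hepatocyte can only clear "
      f"{ucd['EX_nh3']:.3f} of the offered 0.163 µmol/L/min of ammonia.")
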