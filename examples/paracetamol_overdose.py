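"""Paracetamol overdose: NAPQI-driven loss of liver metabolic functions.

Simulates the PK of paracetamol and its metabolites (saturable
glucuronidation/sulfation plus CYP2E1-mediated NAPQI formation), converts
the liver NAPQI profile into relative activities of four inhibited
targets (THFDH, GDH, ATP synthase, glutathione production) and scans an
FBA objective panel at the paracetamol peak, the NAPQI peak and 24 h.
"""

from hepaflux.scenarios import run_paracetamol

for dose in (1.0, 15.0):
    res = run_paracetamol(dose_g=dose)
    s = res.summaries
    print(f"--- dose {dose:g} g ---")
    print(f"NAPQI peak (liver)    : {s['napqi_cmax_liver_uM']:.1f} µM")
    relE = s["relE_at_napqi_peak"]
    print("relE at NAPQI peak    : " +
          "  ".join(f"{e}={v:.2f}" for e, v in relE.items()))
    print(f"affected objectives   : {s['affected_counts']}")
    dec24 = res.panel_reports["t_24h"].max_decrease()
    print(f"max decrease at 24 h  : {dec24:.2f}")
    print()

print("The therapeutic dose barely dents the panel and recovers within a "
      "day; the 15 g overdose saturates the conjugation routes, NAPQI "
      "persists, and the dependent liver functions remain depressed at 24 h.")
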