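"""From median survival times to a monthly transition matrix.

Builds both strategies' 3-state transition tables from their median
disease-free survival (DFS) and overall survival (OS) alone, with the
+/-20% one-way sensitivity bounds used by the tornado analysis.
"""

from markovcea import probability_table

for label, (median_dfs, median_os) in {
    "Open pancreaticoduodenectomy (OPD)": (14, 22),
    "Laparoscopic pancreaticoduodenectomy (LPD)": (15, 24),
}.items():
    print(f"\n{label}: median DFS {median_dfs} mo, median OS {median_os} mo")
    print(probability_table(median_dfs, median_os).to_string(index=False))

print(
    "\nEach row is a monthly probability: e.g. p_dfs_pd is the chance a"
    "\ndisease-free patient progresses within one month, derived as"
    "\n1 - 0.5**(1/median). Lower/upper are the +/-20% ranges (capped at 1)."
)
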