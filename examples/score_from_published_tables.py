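"""Score arithmetic on published alignment tables.

Each row of a national or per-state alignment table prints two percentages:
the share of acquired land inside priority areas (P_TNC) and the share of
the region covered by priority areas (P_S).  The science influence score
(P_TNC − P_S)/(1 − P_S) normalizes the first against the second, so rows
with very different coverage become comparable.
"""

from prioralign import science_influence_score

ROWS = [
    # label, % acquisition area in priority, % region area in priority
    ("recent acquisitions (2006-2011)", 80.5, 36.4),
    ("undated records", 71.8, 36.4),
    ("conservation easements", 64.2, 36.4),
    ("fee simple acquisitions", 86.1, 36.4),
    ("Maine", 47.2, 29.6),
    ("Kansas", 94.5, 25.1),
]

print(f"{'stratum / state':<34}{'P_TNC':>8}{'P_S':>8}{'score':>8}")
for label, p_tnc_pct, p_s_pct in ROWS:
    score = science_influence_score(p_tnc_pct / 100, p_s_pct / 100)
    print(f"{label:<34}{p_tnc_pct:>7.1f}%{p_s_pct:>7.1f}%{100 * score:>7.1f}%")

print(
    "\nA score of 0% would mean alignment is exactly what uniform-random"
    "\nacquisition gives; 100% means every acquired hectare is inside a"
    "\npriority area.  Fee simple purchases score far above easements."
)
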