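"""Score fish stocks against the harvest-control-rule curve.

Shows how B/B_MSY maps to a 0-1 stock score (penalizing both over- and
under-exploitation), and how catch from unassessed stocks discounts a
region's wild-capture fisheries status.
"""

from ohibc.goals import StockRecord, fisheries_status, stock_score_hcr

print("HCR stock scores (F/F_MSY unknown):")
for b in (0.05, 0.425, 0.8, 1.0, 1.5, 2.25, 3.0):
    print(f"  B/B_MSY = {b:5.3f}  ->  score {stock_score_hcr(b):.3f}")
print("Scores rise from 0 at collapse (0.05) to the plateau [0.8, 1.5]"
      " around the MSY target, then fall to the 0.25 underexploitation floor.")

stocks = [
    StockRecord("hake", "r1", 2016, catch=300, bbmsy=1.0, ffmsy=0.9, assessed=True),
    StockRecord("sole", "r1", 2016, catch=100, bbmsy=0.425, assessed=True),
    StockRecord("misc", "r1", 2016, catch=100),           # unassessed: penalized
    StockRecord("herring", "r1", 2016, catch=500, exempt=True),  # non-MSY managed
]
status = fisheries_status(stocks)
print(f"\nRegion fisheries status: {status:.4f}")
print("= catch-weighted mean of assessed scores (0.875)"
      " x assessed-catch fraction (400/500 = 0.8);"
      " the exempt herring catch is neither scored nor penalized.")
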