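"""Collapse methods into coarser groups before drawing.

Thin switching/quitting flows are easy to over-read; grouping methods into
long-acting, short-acting, and traditional classes shows churn across
higher-order categories instead.
"""

from contraflow import collapse_methods, tutorial_flow_table

table = tutorial_flow_table()
grouping = {
    "implants": "long-acting",
    "injections": "short-acting",
    "pill": "short-acting",
    "condom": "short-acting",
    "rhythm": "traditional",
}
grouped = collapse_methods(table, grouping)
print("grouped flow matrix:")
print(grouped.to_frame().astype(int))
print(f"\nlong-acting row total: {grouped.row_marginal('long-acting'):.0f}")
print(f"grand total preserved: {grouped.grand_total:.0f} == {table.grand_total:.0f}")
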