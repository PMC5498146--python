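"""Profile energy metabolism capability of genome bins via KEGG modules.

For each bin and module the statistic is the fraction of the module's
KO terms found among the bin's annotated genes — deliberately not
normalized by genome size or completeness.  Module definitions are
plain TSV supplied by the user; here we build two small ones inline.
"""

from minimeta import ModuleDefinition, compute_module_ratios

modules = [
    ModuleDefinition("M00175", "nitrogen fixation",
                     frozenset({"K02586", "K02588", "K02591"})),
    ModuleDefinition("M00596", "dissimilatory sulfate reduction",
                     frozenset({"K00394", "K00395", "K11180", "K11181"})),
]
bin_kos = {
    "bin_001": {"K02586", "K02588", "K02591", "K00394"},
    "bin_002": {"K00394", "K00395", "K11180", "K11181"},
    "bin_003": {"K99999"},
}

ratios = compute_module_ratios(bin_kos, modules)
print(ratios.to_string(float_format="%.2f"))
print(
    "1.00 = the bin carries every KO of the module (full capability);\n"
    "0.00 = none.  bin_001 can fix nitrogen but lacks most of the\n"
    "sulfate-reduction machinery; bin_002 is the reverse."
)
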