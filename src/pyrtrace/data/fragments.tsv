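# GC-MS SIM fragment library for 13C-pyruvate tracing.
# Organic acids / amino acids: MOX (methoxime, where a keto group is present)
# + TBDMS derivatives, monitored as the [M-57]+ (tert-butyl loss) ion.
# Glucose: aldonitrile pentapropionate (ALDO), carbons 4-6 fragment
# (curator-supplied formula; the instrument method scans 170-380 m/z).
# sim_window is the published SIM acquisition window (m/z, 1 decimal);
# sim_start_mz is its first channel. Printed windows for alanine, fumarate,
# glutamate, PEP and 3PG differ by 0.1 m/z from the 1-decimal rounding of the
# conventional fragment's computed monoisotopic mass; both are kept, and no
# agreement is forced (see docs/methods.md).
# n_labelable counts the metabolite backbone carbons carried by the fragment.
metabolite	fragment_formula	n_labelable	sim_start_mz	channel_count	sim_window	derivative
pyruvate	C6H12NO3Si	3	174.1	5	174.1-178.1	MOX-TBDMS [M-57]+
lactate	C11H25O3Si2	3	261.1	5	261.1-265.1	2TBDMS [M-57]+
alanine	C11H26NO2Si2	3	260.1	5	260.1-264.1	2TBDMS [M-57]+
succinate	C12H25O4Si2	4	289.1	6	289.1-294.1	2TBDMS [M-57]+
fumarate	C12H23O4Si2	4	287.2	6	287.2-292.2	2TBDMS [M-57]+
akg	C14H28NO5Si2	5	346.2	7	346.2-352.2	MOX-2TBDMS [M-57]+
malate	C18H39O5Si3	4	419.2	6	419.2-424.2	3TBDMS [M-57]+
aspartate	C18H40NO4Si3	4	418.2	6	418.2-423.2	3TBDMS [M-57]+
glutamate	C19H42NO4Si3	5	432.3	6	432.3-437.3	3TBDMS [M-57]+
pep	C17H38O6PSi3	3	453.3	6	453.3-458.3	3TBDMS [M-57]+
citrate_431	C19H39O5Si3	6	431.2	8	431.2-438.2	4TBDMS [M-57-TBDMSOH-CO]+
citrate_459	C20H39O6Si3	6	459.2	8	459.2-466.2	4TBDMS [M-57-TBDMSOH]+
3pg	C23H54O7PSi4	3	585.4	6	585.4-590.4	4TBDMS [M-57]+
glucose_C456	C11H15O7	3	259.1	5	259.1-263.1	ALDO C4-C6
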