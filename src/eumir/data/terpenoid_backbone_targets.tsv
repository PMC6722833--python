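target_id	miRNAs	annotation
c146902.graph_c0	n-eu-miR39	geranylgeranyl diphosphate reductase
c128958.graph_c4	n-eu-miR85	ditrans,polycis-polyprenyl diphosphate synthase
c134980.graph_c0	n-eu-miR5	ditrans,polycis-polyprenyl diphosphate synthase
c130182.graph_c1	n-eu-miR45	1-deoxy-D-xylulose-5-phosphate reductoisomerase
c138767.graph_c0	n-eu-miR65	1-deoxy-D-xylulose-5-phosphate synthase
c132996.graph_c3	eu-miR156f-5p	prenyl protein peptidase
c148011.graph_c0	n-eu-miR76	geranylgeranyl diphosphate synthase, type II
c130198.graph_c0	eu-miR156f-3p	farnesyl diphosphate synthase
c139976.graph_c0	n-eu-miR42	geranylgeranyl diphosphate synthase, type II
c124585.graph_c0	n-eu-miR43	hydroxymethylglutaryl-CoA reductase (NADPH)
c137756.graph_c2	n-eu-miR91	phosphomevalonate kinase
c96211.graph_c0	n-eu-miR42	endopeptidase
c136111.graph_c2	n-eu-miR42; n-eu-miR152	farnesyl diphosphate synthase
c122494.graph_c0	n-eu-miR1; n-eu-miR8	acetyl-CoA C-acetyltransferase
c138663.graph_c0	eu-miR396b; n-eu-miR60	diphosphomevalonate decarboxylase
c126798.graph_c1	n-eu-miR85; n-eu-miR47	prenylcysteine alpha-carboxyl methylesterase
c133948.graph_c0	eu-miR396c-3p; n-eu-miR15; n-eu-miR109	geranylgeranyl diphosphate synthase, type II
c136533.graph_c5	eu-miR156b; n-eu-miR66; n-eu-miR101; n-eu-miR147	farnesyl diphosphate synthase
c121732.graph_c0	eu-miR2111a-5p; n-eu-miR1; n-eu-miR8; n-eu-miR66	1-deoxy-D-xylulose-5-phosphate synthase
c139224.graph_c1	eu-miR156b; n-eu-miR43; n-eu-miR59; n-eu-miR108	prenylcysteine oxidase / farnesylcysteine lyase
c136892.graph_c1	n-eu-miR1; n-eu-miR4; n-eu-miR94; n-eu-miR95; n-eu-miR142; n-eu-miR152	all-trans-nonaprenyl-diphosphate synthase
c137351.graph_c2	n-eu-miR1; n-eu-miR7; n-eu-miR8; n-eu-miR33; n-eu-miR43; n-eu-miR45; n-eu-miR76; n-eu-miR78; n-eu-miR152	isopentenyl-diphosphate delta-isomerase
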