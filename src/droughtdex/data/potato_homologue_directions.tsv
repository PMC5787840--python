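# Cross-species direction calls for the 23 top-ranking potato
# drought-responsive genes and their Arabidopsis/rice homologues,
# transcribed from the published comparison. Symbols are relative to the
# potato gene's drought response: up/down arrow = same direction,
# en dash = no significant change, nd = no data, ≠ = opposite direction.
potato_gene	pair	arabidopsis_gene	rice_gene	arabidopsis_symbol	rice_symbol
PGSC0003DMG400001621	Gwiazda/Oberon	AT4G38690	LOC_Os09g36520	↗	↗
PGSC0003DMG400012174	Gwiazda/Oberon	AT1G64110	LOC_Os01g12660	–	↗
PGSC0003DMG400014293	Gwiazda/Oberon	AT5G52300	LOC_Os10g36180	–	↗
PGSC0003DMG400015019	Gwiazda/Oberon	AT5G55090	LOC_Os02g21700	–	nd
PGSC0003DMG400024849	Gwiazda/Oberon	AT1G77120	LOC_Os11g10480	–	↗
PGSC0003DMG401015935	Gwiazda/Oberon	AT4G33150	LOC_Os02g54254	–	↗
PGSC0003DMG400000723	Gwiazda/Oberon	AT4G34490	LOC_Os03g51250	–	nd
PGSC0003DMG400002943	Gwiazda/Oberon	AT3G11170	No homologue	–	nd
PGSC0003DMG400020629	Gwiazda/Oberon	AT1G22170	LOC_Os02g51590	–	nd
PGSC0003DMG400001771	Tajfun/Owacja	AT3G09720	LOC_Os07g45360	–	≠
PGSC0003DMG400003688	Tajfun/Owacja	AT1G19530	LOC_Os03g61150	↗	↗
PGSC0003DMG400005731	Tajfun/Owacja	AT3G18280	LOC_Os05g47700	↗	↗
PGSC0003DMG400005917	Tajfun/Owacja	AT3G49400	LOC_Os01g50690	↗	nd
PGSC0003DMG400008497	Tajfun/Owacja	AT3G51810	LOC_Os05g28210	–	↗
PGSC0003DMG400019233	Tajfun/Owacja	AT3G20660	LOC_Os04g53930	↗	↗
PGSC0003DMG400024093	Tajfun/Owacja	No homologue	LOC_Os02g33820	nd	↗
PGSC0003DMG400039484	Tajfun/Owacja	AT1G59860	LOC_Os03g16030	–	↗
PGSC0003DMG400006913	Tajfun/Owacja	AT5G14570	LOC_Os01g50820	–	↘
PGSC0003DMG400007427	Tajfun/Owacja	AT3G05410	LOC_Os01g70820	↘	↘
PGSC0003DMG400008018	Tajfun/Owacja	AT5G09640	LOC_Os11g27264	–	nd
PGSC0003DMG400014954	Tajfun/Owacja	AT4G31940	No homologue	–	nd
PGSC0003DMG400022225	Tajfun/Owacja	AT4G27030	LOC_Os08g08850	↘	↘
PGSC0003DMG400023602	Tajfun/Owacja	AT4G16490	LOC_Os07g39590	≠	↘
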