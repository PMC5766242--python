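symbol	entrez_id	level1	level2	role	atp
PSMA1	600001	proteasome	20S-alpha	co-chaperone	not-applicable
PSMA2	600002	proteasome	20S-alpha	co-chaperone	not-applicable
PSMA3	600003	proteasome	20S-alpha	co-chaperone	not-applicable
PSMA4	600004	proteasome	20S-alpha	co-chaperone	not-applicable
PSMA5	600005	proteasome	20S-alpha	co-chaperone	not-applicable
PSMA6	600006	proteasome	20S-alpha	co-chaperone	not-applicable
PSMA7	600007	proteasome	20S-alpha	co-chaperone	not-applicable
PSMB1	600008	proteasome	20S-beta	co-chaperone	not-applicable
PSMB2	600009	proteasome	20S-beta	co-chaperone	not-applicable
PSMB3	600010	proteasome	20S-beta	co-chaperone	not-applicable
PSMB4	600011	proteasome	20S-beta	co-chaperone	not-applicable
PSMB5	600012	proteasome	20S-beta	co-chaperone	not-applicable
PSMB6	600013	proteasome	20S-beta	co-chaperone	not-applicable
PSMB7	600014	proteasome	20S-beta	co-chaperone	not-applicable
PSMB8	600015	proteasome	20S-beta	co-chaperone	not-applicable
PSMB9	600016	proteasome	20S-beta	co-chaperone	not-applicable
PSMB10	600017	proteasome	20S-beta	co-chaperone	not-applicable
PSMB11	600018	proteasome	20S-beta	co-chaperone	not-applicable
PSMC1	600019	proteasome	19S-ATPase	co-chaperone	not-applicable
PSMC2	600020	proteasome	19S-ATPase	co-chaperone	not-applicable
PSMC3	600021	proteasome	19S-ATPase	co-chaperone	not-applicable
PSMC4	600022	proteasome	19S-ATPase	co-chaperone	not-applicable
PSMC5	600023	proteasome	19S-ATPase	co-chaperone	not-applicable
PSMC6	600024	proteasome	19S-ATPase	co-chaperone	not-applicable
PSMD1	600025	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD2	600026	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD3	600027	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD4	600028	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD5	600029	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD6	600030	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD7	600031	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD8	600032	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD9	600033	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD10	600034	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD11	600035	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD12	600036	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD13	600037	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSMD14	600038	proteasome	19S-non-ATPase	co-chaperone	not-applicable
PSME1	600039	proteasome	activator	co-chaperone	not-applicable
PSME2	600040	proteasome	activator	co-chaperone	not-applicable
PSME3	600041	proteasome	activator	co-chaperone	not-applicable
PSME4	600042	proteasome	activator	co-chaperone	not-applicable
PSMF1	600043	proteasome	inhibitor	co-chaperone	not-applicable
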