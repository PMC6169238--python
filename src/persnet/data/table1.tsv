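id	geo_accession	plant	stress_group	stress
1	GSE12856	Arabidopsis	PTI	Nonhost
2	GSE13739	Arabidopsis	Induced resistance	Induced resistance (SA)
3	GSE14961	Arabidopsis	Induced resistance	Induced resistance (SA)
4	GSE15236	Arabidopsis	Fungi	Fusarium oxysporum
5	GSE16471	Arabidopsis	PTI	PTI
6	GSE16472	Arabidopsis	PTI	PTI
7	GSE16497	Arabidopsis	Induced resistance	Induced resistance (Aphid)
8	GSE17382	Arabidopsis	PTI	PTI
9	GSE17875	Arabidopsis	Fungi	Botrytis cinerea
10	GSE19273	Arabidopsis	Bacteria	Ralstonia solanacearum
11	GSE20188	Arabidopsis	Induced resistance	Induced resistance (insecticides)
12	GSE21762	Arabidopsis	Induced resistance	Induced resistance (JA)
13	GSE21920	Arabidopsis	Bacteria	Pseudomonas syringae
14	GSE26679	Arabidopsis	Fungi	Golovinomyces cichoracearum
15	GSE26973	Arabidopsis	Induced resistance	Induced resistance (exudates)
16	GSE28800	Arabidopsis	Induced resistance	Induced resistance (chemistry)
17	GSE431	Arabidopsis	Fungi	Erysiphe cichoracearum
18	GSE5513	Arabidopsis	PTI	Induced resistance (PTI)
19	GSE5752	Arabidopsis	Induced resistance	Induced resistance (SA)
20	GSE5753	Arabidopsis	Induced resistance	Induced resistance (SA)
21	GSE5754	Arabidopsis	Induced resistance	Induced resistance (SA)
22	GSE5755	Arabidopsis	Induced resistance	Induced resistance (SA)
23	GSE5756	Arabidopsis	Induced resistance	Induced resistance (SA)
24	GSE5757	Arabidopsis	Induced resistance	Induced resistance (SA)
25	GSE5758	Arabidopsis	Induced resistance	Induced resistance (SA)
26	GSE6831	Arabidopsis	Induced resistance	SAR(JA)
27	GSE8319	Arabidopsis	PTI	PTI
28	GSE10426	Arabidopsis	Fungi	Plasmodiophora brassicae
29	GSE10713	Arabidopsis	Fungi	Fusarium oxysporum pv. raphani
30	GSE13390	Arabidopsis	Bacteria	Pseudomonas syringae pv. tomato
31	GSE15880	Arabidopsis	Fungi	Botrytis cinerea
32	GSE15881	Arabidopsis	Fungi	Botrytis cinerea
33	GSE18757	Arabidopsis	Bacteria	Ralstonia solanacearum
34	GSE25838	Arabidopsis	Fungi	Botrytis cinerea
35	GSE34081	Arabidopsis	Bacteria	Pseudomonas syringae pv. tomato
36	GSE7990	Arabidopsis	Induced resistance	Induced resistance (ISR, Bradyrhizobium)
37	GSE8877	Arabidopsis	Fungi	Plasmodiophora brassicae
38	GSE31230	Arabidopsis	Bacteria	Ralstonia solanacearum
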