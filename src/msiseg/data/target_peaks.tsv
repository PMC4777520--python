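mz	label	class	flagged_duplicate
74.65	unknown m/z 74.65	unknown	false
104.11	choline [M+H]+	lipid	false
118.28	unknown m/z 118.28	unknown	false
175.33	unknown m/z 175.33	unknown	false
184.07	phosphocholine [M+H]+	lipid	false
230.00	unknown m/z 230.00	unknown	false
277.17	coumaroylagmatine [M+H]+	secondary	false
293.16	coumaroyl-hydroxyagmatine [M+H]+	secondary	false
307.18	feruloylagmatine [M+H]+	secondary	false
323.17	feruloyl-hydroxyagmatine [M+H]+	secondary	false
381.08	hexose DP2 [M+K]+	oligosaccharide	false
496.34	PC(16:0) [M+H]+	lipid	false
518.32	PC(16:0) [M+Na]+	lipid	false
520.34	PC(18:2) [M+H]+	lipid	false
527.16	hexose DP3 [M+Na]+	oligosaccharide	false
534.09	PC(16:0) [M+K]+	lipid	false
543.13	hexose DP3 [M+K]+	oligosaccharide	false
551.31	hordatine A [M+H]+	secondary	false
558.18	unknown m/z 558.18	unknown	false
567.30	hydroxy-hordatine A [M+H]+	secondary	false
573.29	hordatine A [M+Na]+	secondary	false
581.32	hordatine B [M+H]+	secondary	false
589.26	hordatine A [M+K]+	secondary	false
589.29	hydroxy-hordatine A [M+Na]+	secondary	true
597.31	hydroxy-hordatine B [M+H]+	secondary	false
603.30	hordatine B [M+Na]+	secondary	false
605.26	hydroxy-hordatine A [M+K]+	secondary	false
611.33	hordatine C [M+H]+	secondary	false
619.28	hordatine B [M+K]+	secondary	false
619.30	hydroxy-hordatine B [M+Na]+	secondary	true
627.32	hydroxy-hordatine C [M+H]+	secondary	false
635.27	hydroxy-hordatine B [M+K]+	secondary	false
650.55	unknown m/z 650.55	unknown	false
674.38	unknown m/z 674.38	unknown	false
689.21	hexose DP4 [M+Na]+	oligosaccharide	false
705.18	hexose DP4 [M+K]+	oligosaccharide	false
713.36	hordatine A + Hex [M+H]+	secondary	false
729.36	hydroxy-hordatine A + Hex [M+H]+	secondary	false
735.34	hordatine A + Hex [M+Na]+	secondary	false
743.37	hordatine B + Hex [M+H]+	secondary	false
751.32	hordatine A + Hex [M+K]+	secondary	false
751.34	hydroxy-hordatine A + Hex [M+Na]+	secondary	true
756.55	PC(34:3) [M+H]+	lipid	false
758.57	PC(34:2) [M+H]+	lipid	false
759.37	hydroxy-hordatine B + Hex [M+H]+	secondary	false
765.35	hordatine B + Hex [M+Na]+	secondary	false
767.31	hydroxy-hordatine A + Hex [M+K]+	secondary	false
773.38	hordatine C + Hex [M+H]+	secondary	false
780.55	PC(36:5) [M+H]+	lipid	false
781.33	hordatine B + Hex [M+K]+	secondary	false
781.35	hydroxy-hordatine B + Hex [M+Na]+	secondary	true
782.57	PC(34:1) [M+Na]+	lipid	false
782.66	PC(36:4) [M+H]+	lipid	true
789.38	hydroxy-hordatine C + Hex [M+H]+	secondary	false
795.36	hordatine C + Hex [M+Na]+	secondary	false
796.52	PC(34:2) [M+K]+	lipid	false
797.32	hydroxy-hordatine B + Hex [M+K]+	secondary	false
811.34	hordatine C + Hex [M+K]+	secondary	false
811.36	hydroxy-hordatine C + Hex [M+Na]+	secondary	true
820.53	PC(36:4) [M+K]+	lipid	false
827.33	hydroxy-hordatine C + Hex [M+K]+	secondary	false
851.26	hexose DP5 [M+Na]+	oligosaccharide	false
867.24	hexose DP5 [M+K]+	oligosaccharide	false
875.41	hordatine A + 2 Hex [M+H]+	secondary	false
891.41	hydroxy-hordatine A + 2 Hex [M+H]+	secondary	false
897.40	hordatine A + 2 Hex [M+Na]+	secondary	false
897.73	TG(52:2) [M+K]+	lipid	false
905.43	hordatine B + 2 Hex [M+H]+	secondary	false
913.37	hordatine A + 2 Hex [M+K]+	secondary	false
913.39	hydroxy-hordatine A + 2 Hex [M+Na]+	secondary	true
921.42	hydroxy-hordatine B + 2 Hex [M+H]+	secondary	false
927.41	hordatine B + 2 Hex [M+Na]+	secondary	false
929.37	hydroxy-hordatine A + 2 Hex [M+K]+	secondary	false
935.44	hordatine C + 2 Hex [M+H]+	secondary	false
943.38	hordatine B + 2 Hex [M+K]+	secondary	false
943.40	hydroxy-hordatine B + 2 Hex [M+Na]+	secondary	true
951.43	hydroxy-hordatine C + 2 Hex [M+H]+	secondary	false
955.57	PI(40:3) [M+K]+	lipid	false
957.42	hordatine C + 2 Hex [M+Na]+	secondary	false
959.38	hydroxy-hordatine B + 2 Hex [M+K]+	secondary	false
963.60	PI(42:5) [M+Na]+	lipid	false
973.39	hordatine C + 2 Hex [M+K]+	secondary	false
973.41	hydroxy-hordatine C + 2 Hex [M+Na]+	secondary	true
979.57	PI(42:5) [M+K]+	lipid	false
989.39	hydroxy-hordatine C + 2 Hex [M+K]+	secondary	false
1006.58	unknown m/z 1006.58	unknown	false
1013.31	hexose DP6 [M+Na]+	oligosaccharide	false
1029.29	hexose DP6 [M+K]+	oligosaccharide	false
1175.37	hexose DP7 [M+Na]+	oligosaccharide	false
1191.34	hexose DP7 [M+K]+	oligosaccharide	false
1337.42	hexose DP8 [M+Na]+	oligosaccharide	false
1353.40	hexose DP8 [M+K]+	oligosaccharide	false
1499.47	hexose DP9 [M+Na]+	oligosaccharide	false
1515.45	hexose DP9 [M+K]+	oligosaccharide	false
1661.53	hexose DP10 [M+Na]+	oligosaccharide	false
1677.51	hexose DP10 [M+K]+	oligosaccharide	false
1823.58	hexose DP11 [M+Na]+	oligosaccharide	false
1839.56	hexose DP11 [M+K]+	oligosaccharide	false
1986.10	hexose DP12 [M+Na]+	oligosaccharide	false
2001.74	hexose DP12 [M+K]+	oligosaccharide	false
2148.05	hexose DP13 [M+Na]+	oligosaccharide	false
2163.91	hexose DP13 [M+K]+	oligosaccharide	false
2200.69	unknown m/z 2200.69	unknown	false
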