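name	sequence	organism	citation
Strigaibol A	Ac-Aib-Ser-Aib-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Vxx-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Lxxol	Trichoderma strigosum	park2023
Strigaibol B	Ac-Aib-Ser-Aib-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Lxxol	Trichoderma strigosum	park2023
Strigaibol C	Ac-Aib-Ser-Aib-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Lxxol	Trichoderma strigosum	park2023
Strigaibol D	Ac-Aib-Ala-Aib-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Vxx-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Lxxol	Trichoderma strigosum	park2023
Strigaibol E	Ac-Aib-Ala-Aib-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Lxxol	Trichoderma strigosum	park2023
Strigaibol F	Ac-Aib-Ala-Aib-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Vxx-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Lxxol	Trichoderma strigosum	park2023
Strigaibol G	Ac-Aib-Ala-Aib-Aib-Lxx-Gln-Aib-Aib-Aib-Ala-Lxx-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Lxxol	Trichoderma strigosum	park2023
Strigaibol H	Ac-Aib-Aib-Aib-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Lxxol	Trichoderma strigosum	park2023
Tricholongin LBI	Ac-Aib-Gly-Phe-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Lxxol	Trichoderma longibrachiatum	degenkolb2020
Tricholongin LBII	Ac-Aib-Gly-Phe-Aib-Aib-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Vxx-Gln-Gln-Lxxol	Trichoderma longibrachiatum	degenkolb2020
Trikoningin KA V	Ac-Aib-Gly-Ala-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Lxx-Gln-Gln-Lxxol	Trichoderma koningii	goulard1995
Trichogin GB IX	Oc-Aib-Gly-Lxx-Aib-Gly-Gly-Lxx-Aib-Gly-Gly-Lxx-Aib-Gly-Lxx-Lxxol	Trichoderma longibrachiatum	auvinguette1992
Lipostrigocin LSG A3	Oc-Aib-Gly-Lxx-Aib-Gly-Lxx-Lxxol	Trichoderma strigosellum	degenkolb2020
Lipostrigocin LSG B3	Oc-Aib-Gly-Vxx-Aib-Gly-Gly-Vxx-Aib-Gly-Lxx-Lxxol	Trichoderma strigosellum	degenkolb2020
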