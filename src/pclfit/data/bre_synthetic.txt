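# SYNTHETIC stand-in contact potential (label: bre). Constructed as
# -2*h_a*h_b from the Kyte-Doolittle hydrophobicity scale rescaled to
# [0,1]; NOT the published empirical contact-energy matrix it stands in
# for. Replace via load_energy_model(path=...) to use the real table.
#        A      C      D      E      F      G      H      I      K      L      M      N      P      Q      R      S      T      V      W      Y
A  -0.98  -1.09  -0.16  -0.16  -1.14  -0.64  -0.20  -1.40  -0.09  -1.29  -1.00  -0.16  -0.45  -0.16  -0.00  -0.58  -0.59  -1.35  -0.56  -0.50
C  -1.09  -1.21  -0.17  -0.17  -1.26  -0.71  -0.23  -1.56  -0.10  -1.44  -1.11  -0.17  -0.50  -0.17  -0.00  -0.64  -0.66  -1.50  -0.62  -0.55
D  -0.16  -0.17  -0.03  -0.03  -0.18  -0.10  -0.03  -0.22  -0.01  -0.20  -0.16  -0.03  -0.07  -0.03  -0.00  -0.09  -0.09  -0.21  -0.09  -0.08
E  -0.16  -0.17  -0.03  -0.03  -0.18  -0.10  -0.03  -0.22  -0.01  -0.20  -0.16  -0.03  -0.07  -0.03  -0.00  -0.09  -0.09  -0.21  -0.09  -0.08
F  -1.14  -1.26  -0.18  -0.18  -1.32  -0.74  -0.23  -1.62  -0.11  -1.50  -1.15  -0.18  -0.52  -0.18  -0.00  -0.67  -0.69  -1.57  -0.65  -0.58
G  -0.64  -0.71  -0.10  -0.10  -0.74  -0.41  -0.13  -0.91  -0.06  -0.84  -0.65  -0.10  -0.29  -0.10  -0.00  -0.38  -0.39  -0.88  -0.36  -0.32
H  -0.20  -0.23  -0.03  -0.03  -0.23  -0.13  -0.04  -0.29  -0.02  -0.27  -0.20  -0.03  -0.09  -0.03  -0.00  -0.12  -0.12  -0.28  -0.12  -0.10
I  -1.40  -1.56  -0.22  -0.22  -1.62  -0.91  -0.29  -2.00  -0.13  -1.84  -1.42  -0.22  -0.64  -0.22  -0.00  -0.82  -0.84  -1.93  -0.80  -0.71
K  -0.09  -0.10  -0.01  -0.01  -0.11  -0.06  -0.02  -0.13  -0.01  -0.12  -0.10  -0.01  -0.04  -0.01  -0.00  -0.06  -0.06  -0.13  -0.05  -0.05
L  -1.29  -1.44  -0.20  -0.20  -1.50  -0.84  -0.27  -1.84  -0.12  -1.70  -1.31  -0.20  -0.59  -0.20  -0.00  -0.76  -0.78  -1.78  -0.74  -0.66
M  -1.00  -1.11  -0.16  -0.16  -1.15  -0.65  -0.20  -1.42  -0.10  -1.31  -1.01  -0.16  -0.46  -0.16  -0.00  -0.58  -0.60  -1.38  -0.57  -0.51
N  -0.16  -0.17  -0.03  -0.03  -0.18  -0.10  -0.03  -0.22  -0.01  -0.20  -0.16  -0.03  -0.07  -0.03  -0.00  -0.09  -0.09  -0.21  -0.09  -0.08
P  -0.45  -0.50  -0.07  -0.07  -0.52  -0.29  -0.09  -0.64  -0.04  -0.59  -0.46  -0.07  -0.21  -0.07  -0.00  -0.27  -0.27  -0.62  -0.26  -0.23
Q  -0.16  -0.17  -0.03  -0.03  -0.18  -0.10  -0.03  -0.22  -0.01  -0.20  -0.16  -0.03  -0.07  -0.03  -0.00  -0.09  -0.09  -0.21  -0.09  -0.08
R  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00  -0.00
S  -0.58  -0.64  -0.09  -0.09  -0.67  -0.38  -0.12  -0.82  -0.06  -0.76  -0.58  -0.09  -0.27  -0.09  -0.00  -0.34  -0.35  -0.80  -0.33  -0.29
T  -0.59  -0.66  -0.09  -0.09  -0.69  -0.39  -0.12  -0.84  -0.06  -0.78  -0.60  -0.09  -0.27  -0.09  -0.00  -0.35  -0.36  -0.82  -0.34  -0.30
V  -1.35  -1.50  -0.21  -0.21  -1.57  -0.88  -0.28  -1.93  -0.13  -1.78  -1.38  -0.21  -0.62  -0.21  -0.00  -0.80  -0.82  -1.87  -0.77  -0.69
W  -0.56  -0.62  -0.09  -0.09  -0.65  -0.36  -0.12  -0.80  -0.05  -0.74  -0.57  -0.09  -0.26  -0.09  -0.00  -0.33  -0.34  -0.77  -0.32  -0.28
Y  -0.50  -0.55  -0.08  -0.08  -0.58  -0.32  -0.10  -0.71  -0.05  -0.66  -0.51  -0.08  -0.23  -0.08  -0.00  -0.29  -0.30  -0.69  -0.28  -0.25
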