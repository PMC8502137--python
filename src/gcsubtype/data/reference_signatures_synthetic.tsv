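# Synthetic emulation of four reference mutational signatures (NOT the curated COSMIC tables); regenerate with `python -m gcsubtype.resources`.
channel	Signature 1	Signature 6	Signature 17	Signature 29
A[C>A]A	0.00031250	0.00443352	0.00031250	0.05948635
A[C>A]C	0.00031250	0.00443352	0.00031250	0.03590014
A[C>A]G	0.00031250	0.00443352	0.00031250	0.01231394
A[C>A]T	0.00031250	0.00443352	0.00031250	0.02410704
C[C>A]A	0.00031250	0.00443352	0.00031250	0.17741739
C[C>A]C	0.00031250	0.00443352	0.00031250	0.10665876
C[C>A]G	0.00031250	0.00443352	0.00031250	0.03590014
C[C>A]T	0.00031250	0.00443352	0.00031250	0.07127945
G[C>A]A	0.00031250	0.00443352	0.00031250	0.05948635
G[C>A]C	0.00031250	0.00443352	0.00031250	0.03590014
G[C>A]G	0.00031250	0.00443352	0.00031250	0.01231394
G[C>A]T	0.00031250	0.00443352	0.00031250	0.02410704
T[C>A]A	0.00031250	0.00443352	0.00031250	0.11845187
T[C>A]C	0.00031250	0.00443352	0.00031250	0.07127945
T[C>A]G	0.00031250	0.00443352	0.00031250	0.02410704
T[C>A]T	0.00031250	0.00443352	0.00031250	0.04769325
A[C>G]A	0.00031250	0.00052083	0.00031250	0.00314152
A[C>G]C	0.00031250	0.00052083	0.00031250	0.00314152
A[C>G]G	0.00031250	0.00052083	0.00031250	0.00314152
A[C>G]T	0.00031250	0.00052083	0.00031250	0.00314152
C[C>G]A	0.00031250	0.00052083	0.00031250	0.00314152
C[C>G]C	0.00031250	0.00052083	0.00031250	0.00314152
C[C>G]G	0.00031250	0.00052083	0.00031250	0.00314152
C[C>G]T	0.00031250	0.00052083	0.00031250	0.00314152
G[C>G]A	0.00031250	0.00052083	0.00031250	0.00314152
G[C>G]C	0.00031250	0.00052083	0.00031250	0.00314152
G[C>G]G	0.00031250	0.00052083	0.00031250	0.00314152
G[C>G]T	0.00031250	0.00052083	0.00031250	0.00314152
T[C>G]A	0.00031250	0.00052083	0.00031250	0.00314152
T[C>G]C	0.00031250	0.00052083	0.00031250	0.00314152
T[C>G]G	0.00031250	0.00052083	0.00031250	0.00314152
T[C>G]T	0.00031250	0.00052083	0.00031250	0.00314152
A[C>T]A	0.00595203	0.02399695	0.00031250	0.00052083
A[C>T]C	0.00595203	0.02399695	0.00031250	0.00052083
A[C>T]G	0.22589390	0.00365098	0.00031250	0.00052083
A[C>T]T	0.00595203	0.01617157	0.00031250	0.00052083
C[C>T]A	0.00595203	0.04747306	0.00031250	0.00052083
C[C>T]C	0.00595203	0.04747306	0.00031250	0.00052083
C[C>T]G	0.22589390	0.00678113	0.00031250	0.00052083
C[C>T]T	0.00595203	0.03182232	0.00031250	0.00052083
G[C>T]A	0.00595203	0.23528195	0.00031250	0.00052083
G[C>T]C	0.00595203	0.23528195	0.00031250	0.00052083
G[C>T]G	0.22589390	0.03182232	0.00031250	0.00052083
G[C>T]T	0.00595203	0.15702825	0.00031250	0.00052083
T[C>T]A	0.00595203	0.01225889	0.00031250	0.00052083
T[C>T]C	0.00595203	0.01225889	0.00031250	0.00052083
T[C>T]G	0.22589390	0.00208591	0.00031250	0.00052083
T[C>T]T	0.00595203	0.00834620	0.00031250	0.00052083
A[T>A]A	0.00031250	0.00052083	0.00031250	0.00052083
A[T>A]C	0.00031250	0.00052083	0.00031250	0.00052083
A[T>A]G	0.00031250	0.00052083	0.00031250	0.00052083
A[T>A]T	0.00031250	0.00052083	0.00031250	0.00052083
C[T>A]A	0.00031250	0.00052083	0.00031250	0.00052083
C[T>A]C	0.00031250	0.00052083	0.00031250	0.00052083
C[T>A]G	0.00031250	0.00052083	0.00031250	0.00052083
C[T>A]T	0.00031250	0.00052083	0.00031250	0.00052083
G[T>A]A	0.00031250	0.00052083	0.00031250	0.00052083
G[T>A]C	0.00031250	0.00052083	0.00031250	0.00052083
G[T>A]G	0.00031250	0.00052083	0.00031250	0.00052083
G[T>A]T	0.00031250	0.00052083	0.00031250	0.00052083
T[T>A]A	0.00031250	0.00052083	0.00031250	0.00052083
T[T>A]C	0.00031250	0.00052083	0.00031250	0.00052083
T[T>A]G	0.00031250	0.00052083	0.00031250	0.00052083
T[T>A]T	0.00031250	0.00052083	0.00031250	0.00052083
A[T>C]A	0.00031250	0.00052083	0.00123442	0.00052083
A[T>C]C	0.00031250	0.00052083	0.00123442	0.00052083
A[T>C]G	0.00031250	0.00052083	0.00123442	0.00052083
A[T>C]T	0.00031250	0.00052083	0.00123442	0.00052083
C[T>C]A	0.00031250	0.00052083	0.00123442	0.00052083
C[T>C]C	0.00031250	0.00052083	0.00123442	0.00052083
C[T>C]G	0.00031250	0.00052083	0.00123442	0.00052083
C[T>C]T	0.00031250	0.00052083	0.00123442	0.00052083
G[T>C]A	0.00031250	0.00052083	0.00123442	0.00052083
G[T>C]C	0.00031250	0.00052083	0.00123442	0.00052083
G[T>C]G	0.00031250	0.00052083	0.00123442	0.00052083
G[T>C]T	0.00031250	0.00052083	0.00123442	0.00052083
T[T>C]A	0.00031250	0.00052083	0.00123442	0.00052083
T[T>C]C	0.00031250	0.00052083	0.00123442	0.00052083
T[T>C]G	0.00031250	0.00052083	0.00123442	0.00052083
T[T>C]T	0.00031250	0.00052083	0.00123442	0.00052083
A[T>G]A	0.00031250	0.00052083	0.00187977	0.00052083
A[T>G]C	0.00031250	0.00052083	0.00187977	0.00052083
A[T>G]G	0.00031250	0.00052083	0.00187977	0.00052083
A[T>G]T	0.00031250	0.00052083	0.07867585	0.00052083
C[T>G]A	0.00031250	0.00052083	0.01285064	0.00052083
C[T>G]C	0.00031250	0.00052083	0.01285064	0.00052083
C[T>G]G	0.00031250	0.00052083	0.01285064	0.00052083
C[T>G]T	0.00031250	0.00052083	0.62721931	0.00052083
G[T>G]A	0.00031250	0.00052083	0.00109613	0.00052083
G[T>G]C	0.00031250	0.00052083	0.00109613	0.00052083
G[T>G]G	0.00031250	0.00052083	0.00109613	0.00052083
G[T>G]T	0.00031250	0.00052083	0.03949418	0.00052083
T[T>G]A	0.00031250	0.00052083	0.00344703	0.00052083
T[T>G]C	0.00031250	0.00052083	0.00344703	0.00052083
T[T>G]G	0.00031250	0.00052083	0.00344703	0.00052083
T[T>G]T	0.00031250	0.00052083	0.15703920	0.00052083
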