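# Italian crude suicide rates per 100,000 inhabitants, total population, 1873-2010.
# Elaborated from ISTAT judicial statistics, 'Suicidi e Tentativi di Suicidio'
# (series excludes prison suicides and deaths occurring days after the act).
# Transcribed at the 2-decimal precision of the published table; the running
# cumulative sum of this column reproduces the published cumulative series exactly.
year,rate
1873,3.43
1874,3.55
1875,3.21
1876,3.54
1877,3.90
1878,3.95
1879,4.14
1880,4.27
1881,4.51
1882,4.63
1883,4.82
1884,4.49
1885,4.74
1886,3.96
1887,4.65
1888,5.07
1889,4.63
1890,5.20
1891,5.30
1892,5.35
1893,5.36
1894,5.31
1895,5.72
1896,6.07
1897,5.71
1898,6.17
1899,6.00
1900,6.05
1901,5.92
1902,5.85
1903,5.56
1904,6.18
1905,6.77
1906,6.54
1907,6.84
1908,7.47
1909,8.16
1910,7.83
1911,7.43
1912,8.02
1913,8.34
1914,8.42
1915,8.10
1916,6.64
1917,6.44
1918,7.10
1919,7.05
1920,7.11
1921,7.61
1922,7.91
1923,8.34
1924,9.69
1925,9.34
1926,9.76
1927,10.52
1928,9.67
1929,8.87
1930,9.55
1931,10.03
1932,9.76
1933,8.85
1934,8.72
1935,7.67
1936,7.92
1937,7.61
1938,7.22
1939,6.87
1940,5.91
1941,5.27
1942,5.22
1943,4.89
1944,3.88
1945,4.67
1946,5.21
1947,5.73
1948,6.15
1949,6.48
1950,6.32
1951,6.67
1952,6.24
1953,6.37
1954,6.00
1955,6.60
1956,6.31
1957,6.12
1958,5.88
1959,6.08
1960,5.86
1961,5.48
1962,4.89
1963,4.90
1964,5.03
1965,5.05
1966,4.97
1967,5.14
1968,4.92
1969,5.01
1970,4.61
1971,4.63
1972,4.53
1973,4.59
1974,4.20
1975,4.21
1976,4.07
1977,4.46
1978,4.65
1979,4.67
1980,4.66
1981,4.87
1982,5.19
1983,5.01
1984,5.56
1985,6.43
1986,6.54
1987,7.11
1988,6.62
1989,6.29
1990,6.62
1991,5.92
1992,7.09
1993,7.20
1994,6.86
1995,6.82
1996,6.34
1997,6.00
1998,5.90
1999,5.22
2000,5.35
2001,4.95
2002,5.14
2003,5.80
2004,5.58
2005,5.20
2006,5.20
2007,4.80
2008,4.70
2009,5.00
2010,5.02
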