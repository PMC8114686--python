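% Answer-set-programming encoding of the minimal precursor-state problem,
% provided as a drop-in for an external ASP solver (e.g. clingo).  The
% native branch-and-bound solver in sbgnq.precursor is the authoritative
% implementation; this asset documents the equivalent declarative program.
%
% Instance facts (emit from a PDMap):
%   entity(E).                      % one per entity pool
%   product(P, E). reactant(P, E).  % reaction graph, modulations removed
%   process(P).
%   source(P) :- process(P), not has_reactant(P).
%   has_reactant(P) :- reactant(P, _).
%   required(E).                    % config: entities forced into the seed
%   statevars(E, N).                % set state variables, recursive count
%   is_complex(E).                  % 1 if the entity is a complex
%
% Choice: an entity is in the precursor state or not.
{ seed(E) : entity(E) }.

% Reachability under the producibility closure (modulators ignored).
reachable(E) :- seed(E).
reachable(E) :- product(P, E), source(P).
reachable(E) :- product(P, E), process(P), reachable(R) : reactant(P, R).

% Constraints: required entities included; every entity producible.
:- required(E), not seed(E).
:- entity(E), not reachable(E).

% Lexicographic objectives (highest priority first).
#minimize { 1@3, E : seed(E) }.
#minimize { N@2, E : seed(E), statevars(E, N) }.
#minimize { 1@1, E : seed(E), is_complex(E) }.

#show seed/1.
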